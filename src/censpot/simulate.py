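"""Simulation study: K selection and saturation-bias correction.

Synthetic target masks are drawn from a known K-component mixture (K = 2 or
3) whose last component is right-censored at the 16-bit saturation ceiling
S = 65535.  The fixed components mimic a peptide-array diagnosis study:

* K = 2 — background N(8000, 2000^2) with weight 0.8;
* K = 3 — background N(2000, 1000^2) with weight 0.7 and an intermediate
  component N(15000, 6000^2) with weight 0.1.

The foreground component has scale sigma_K = 6000 and its location is set
from the target saturated-pixel fraction ``p_sat`` (10/40/70% of foreground
pixels) through the tail condition ``1 - Phi((S - mu_K)/sigma_K) = p_sat``,
i.e. ``mu_K = S - sigma_K * Phi^{-1}(1 - p_sat)``.  Masks hold 500 pixels;
pixel values are exchangeable within a mask (no spatial spot shape).

Three analysis arms are compared trial by trial on identical data:

* ``GMM0`` — regular mixture fitted to the uncensored data (gold standard);
* ``CGMM`` — censored mixture fitted to the censored data (the method);
* ``GMM1`` — regular mixture fitted to the censored data (the naive arm).

Each arm selects K by BIC (relative-difference rule) and, over the trials in
which K was chosen correctly, parameter estimates are summarised as relative
bias (mean estimate minus truth, divided by truth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .mixture import PixelMask, select_K
from .quantify import apply_censoring

__all__ = ["SimScenario", "SimSummary", "make_scenario", "simulate_mask",
           "relative_bias", "run_experiment", "METHODS"]

METHODS = ("GMM0", "CGMM", "GMM1")

_FIXED = {
    2: {"weights": (0.8, 0.2), "means": (8000.0,), "sds": (2000.0,)},
    3: {"weights": (0.7, 0.1, 0.2), "means": (2000.0, 15000.0),
        "sds": (1000.0, 6000.0)},
}


@dataclass(frozen=True)
class SimScenario:
    """Generating mixture, target saturation fraction and trial plan."""

    K_true: int
    weights: tuple
    means: tuple
    sds: tuple
    p_sat: float
    S: float = 65535.0
    n_pixels: int = 500
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true not in (2, 3):
            raise ValueError("K_true must be 2 or 3")
        if not 0 < self.p_sat < 1:
            raise ValueError("p_sat must be in (0, 1)")
        mu = np.asarray(self.means)
        if np.any(np.diff(mu) <= 0):
            raise ValueError("means must be strictly increasing")
        # derived foreground location must reproduce p_sat exactly
        a = (self.S - self.means[-1]) / self.sds[-1]
        from scipy.special import ndtr
        if abs((1.0 - ndtr(a)) - self.p_sat) > 1e-12:
            raise ValueError("foreground mean inconsistent with p_sat")

    @property
    def param_names(self) -> list[str]:
        names = [f"pi{k + 1}" for k in range(self.K_true - 1)]
        for k in range(self.K_true):
            names += [f"mu{k + 1}", f"sigma{k + 1}"]
        return names

    @property
    def truth(self) -> dict[str, float]:
        out = {f"pi{k + 1}": self.weights[k] for k in range(self.K_true - 1)}
        for k in range(self.K_true):
            out[f"mu{k + 1}"] = self.means[k]
            out[f"sigma{k + 1}"] = self.sds[k]
        return out


def make_scenario(K_true: int, p_sat: float, *, fg_sd: float = 6000.0,
                  S: float = 65535.0, n_pixels: int = 500,
                  n_trials: int = 1000, seed: int = 0,
                  weights=None, means=None, sds=None) -> SimScenario:
    """Scenario with fixed study parameters and the derived foreground mean.

    ``mu_K = S - fg_sd * Phi^{-1}(1 - p_sat)`` so that a fraction ``p_sat``
    of foreground pixels saturates in expectation.  ``weights``/``means``/
    ``sds`` override the fixed non-foreground block (means and sds exclude
    the foreground component, which is always derived).
    """
    if K_true not in (2, 3):
        raise ValueError("K_true must be 2 or 3")
    if not 0 < p_sat < 1:
        raise ValueError("p_sat must be in (0, 1)")
    fixed = _FIXED[K_true]
    w = tuple(weights) if weights is not None else fixed["weights"]
    m = tuple(means) if means is not None else fixed["means"]
    s = tuple(sds) if sds is not None else fixed["sds"]
    mu_K = S - fg_sd * float(ndtri(1.0 - p_sat))
    return SimScenario(K_true=K_true, weights=w, means=m + (mu_K,),
                       sds=s + (fg_sd,), p_sat=p_sat, S=S,
                       n_pixels=n_pixels, n_trials=n_trials, seed=seed)


def simulate_mask(s: SimScenario, rng: np.random.Generator,
                  spot_id: str = "sim") -> tuple[PixelMask, PixelMask]:
    """Draw one mask; returns (uncensored with S=inf, censored at s.S)."""
    labels = rng.choice(s.K_true, size=s.n_pixels, p=np.asarray(s.weights))
    values = rng.normal(np.asarray(s.means)[labels], np.asarray(s.sds)[labels])
    unc = PixelMask(spot_id=spot_id, values=values, S=np.inf)
    cen = PixelMask(spot_id=spot_id, values=apply_censoring(values, s.S), S=s.S)
    return unc, cen


def relative_bias(estimates, truth: float) -> float:
    """(mean(estimates) - truth) / truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least one estimate")
    if truth == 0:
        raise ValueError("relative bias undefined for truth == 0")
    return float((est.mean() - truth) / truth)


@dataclass
class SimSummary:
    """Selection rates and relative biases per analysis arm."""

    scenario: SimScenario
    n_trials: int
    selection_rate: dict = field(default_factory=dict)   # method -> percent
    relative_bias: dict = field(default_factory=dict)    # method -> {param: bias}
    bias_se: dict = field(default_factory=dict)          # method -> {param: SE of bias}
    n_trials_used: dict = field(default_factory=dict)    # method -> correct-K trials
    n_failed: dict = field(default_factory=dict)         # method -> failed fits

    def to_json(self, **kwargs) -> str:
        payload = {
            "K_true": self.scenario.K_true,
            "p_sat": self.scenario.p_sat,
            "S": self.scenario.S,
            "n_pixels": self.scenario.n_pixels,
            "n_trials": self.n_trials,
            "seed": self.scenario.seed,
            "truth": self.scenario.truth,
            "selection_rate_percent": self.selection_rate,
            "relative_bias": self.relative_bias,
            "bias_se": self.bias_se,
            "n_trials_used": self.n_trials_used,
            "n_failed": self.n_failed,
        }
        kwargs.setdefault("sort_keys", True)
        return json.dumps(payload, **kwargs)


def _estimates(fit, K_true: int) -> dict[str, float]:
    p = fit.params
    out = {f"pi{k + 1}": float(p.weights[k]) for k in range(K_true - 1)}
    for k in range(K_true):
        out[f"mu{k + 1}"] = float(p.means[k])
        out[f"sigma{k + 1}"] = float(p.sds[k])
    return out


def run_experiment(s: SimScenario, methods=METHODS, *, criterion: str = "bic",
                   rel_threshold: float = 0.001) -> SimSummary:
    """Run the paired selection/bias experiment for one scenario.

    All requested arms see the same simulated data in every trial (per-trial
    RNG streams spawned from the scenario seed), as in a paired design.
    Relative bias is computed only over trials with correctly selected K;
    failed fits are excluded from both rates and biases but counted.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    streams = np.random.SeedSequence(s.seed).spawn(s.n_trials)
    correct = {m: 0 for m in methods}
    failed = {m: 0 for m in methods}
    est: dict[str, dict[str, list[float]]] = {
        m: {p: [] for p in s.param_names} for m in methods}

    import warnings as _warnings
    for t in range(s.n_trials):
        rng = np.random.default_rng(streams[t])
        unc, cen = simulate_mask(s, rng, spot_id=f"trial{t}")
        for m in methods:
            mask, censored = {
                "GMM0": (unc, False),
                "CGMM": (cen, True),
                "GMM1": (cen, False),
            }[m]
            try:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", RuntimeWarning)
                    fit = select_K(mask, censored, criterion=criterion,
                                   rel_threshold=rel_threshold)
            except Exception:
                failed[m] += 1
                continue
            if fit.K == s.K_true:
                correct[m] += 1
                for name, val in _estimates(fit, s.K_true).items():
                    est[m][name].append(val)

    summary = SimSummary(scenario=s, n_trials=s.n_trials)
    truth = s.truth
    for m in methods:
        n_ok = s.n_trials - failed[m]
        summary.selection_rate[m] = 100.0 * correct[m] / n_ok if n_ok else float("nan")
        summary.n_trials_used[m] = correct[m]
        summary.n_failed[m] = failed[m]
        summary.relative_bias[m] = {}
        summary.bias_se[m] = {}
        for name in s.param_names:
            vals = np.asarray(est[m][name])
            if vals.size:
                summary.relative_bias[m][name] = relative_bias(vals, truth[name])
                se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
                summary.bias_se[m][name] = se / abs(truth[name])
            else:
                summary.relative_bias[m][name] = float("nan")
                summary.bias_se[m][name] = float("nan")
    return summary
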