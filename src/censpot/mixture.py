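"""Gaussian mixtures with an optionally right-censored last component.

Pixel intensities within one target mask are modelled as i.i.d. draws from a
K-component mixture (K <= 3): the first K-1 components are ordinary normals
(background, and possibly an intermediate class for fuzzy edges or donut
holes), while the last — the foreground — may be right-censored at the
scanner saturation threshold S.  Saturated pixels (value exactly S) then
contribute the survival mass ``pi_K * (1 - Phi((S - mu_K)/sigma_K))`` to the
likelihood instead of a density value.

Fitting is by EM.  The E-step computes responsibilities in log space; the
M-step has the usual closed forms for the uncensored components and calls the
censored-normal Newton solver for the last component.  Components are kept
sorted by mean after every M-step (mu_1 < ... < mu_K) for identifiability.
The number of components is chosen by AIC or BIC over K = 1..3, preferring
the smallest K whose criterion is within a relative threshold (default 0.001)
of the best.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, logsumexp

from .censored_normal import (
    _LOG_SQRT_2PI,
    CensoredNormalParams,
    NonIdentifiableError,
    fit_censored_normal,
)

__all__ = [
    "PixelMask",
    "MixtureParams",
    "FitResult",
    "ComponentCollapseError",
    "mixture_density",
    "initialize",
    "e_step",
    "m_step",
    "fit_mixture",
    "select_K",
]

SIGMA_FLOOR_FRAC = 1e-6


class ComponentCollapseError(RuntimeError):
    """A mixture component lost essentially all of its responsibility mass."""

    def __init__(self, component: int):
        self.component = component
        super().__init__(f"mixture component {component + 1} collapsed (no mass)")


def _sigma_floor(S: float, values: np.ndarray) -> float:
    if np.isfinite(S):
        return SIGMA_FLOOR_FRAC * abs(S)
    return SIGMA_FLOOR_FRAC * max(float(np.max(np.abs(values), initial=0.0)), 1.0)


@dataclass(frozen=True)
class PixelMask:
    """Pixel data of one spot's target mask.

    Parameters
    ----------
    spot_id
        Identifier of the spot.
    values
        Pixel intensities in ADU, each in ``[0, S]``.
    S
        Saturation threshold; ``np.inf`` marks genuinely uncensored data.
    coords
        Optional ``(n, 2)`` integer array of 0-based (row, col) pixel
        positions, unique per pixel.
    """

    spot_id: str
    values: np.ndarray
    S: float = 65535.0
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        # image pixels live in [0, S]; simulated draws from the generating
        # mixture may fall below 0, so only the censoring ceiling is enforced
        if np.any(values > self.S):
            raise ValueError("pixel values must not exceed S")
        if self.coords is not None:
            coords = np.asarray(self.coords)
            object.__setattr__(self, "coords", coords)
            if coords.shape != (values.size, 2):
                raise ValueError("coords must be an (n, 2) array")
            if len({(int(r), int(c)) for r, c in coords}) != values.size:
                raise ValueError("coords must be unique")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def n_saturated(self) -> int:
        return int(np.sum(self.values == self.S)) if np.isfinite(self.S) else 0


@dataclass(frozen=True)
class MixtureParams:
    """Mixture parameters theta = (pi, mu, sigma) with mu strictly increasing."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    censored_last: bool = False
    S: float = math.inf

    def __post_init__(self) -> None:
        for name in ("weights", "means", "sds"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        K = self.means.size
        if not (1 <= K <= 3):
            raise ValueError("K must be in {1, 2, 3}")
        if self.weights.size != K or self.sds.size != K:
            raise ValueError("weights, means, sds must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("mixing weights must sum to 1")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("mixing weights must lie in [0, 1]")
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("means must be strictly increasing")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be positive")
        if self.censored_last and not np.isfinite(self.S):
            raise ValueError("censored_last requires a finite S")

    @property
    def K(self) -> int:
        return int(self.means.size)


@dataclass
class FitResult:
    """One EM fit: parameters, responsibilities and model-choice criteria."""

    mask: PixelMask
    params: MixtureParams
    resp: np.ndarray
    loglik: float
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    degenerate_fg: bool = False

    @property
    def K(self) -> int:
        return self.params.K

    @property
    def n_params(self) -> int:
        return 3 * self.K - 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.mask.n)


def _component_logdens(values: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(n, K) matrix of log(pi_k) + log component density at each pixel."""
    y = values[:, None]
    mu = params.means[None, :]
    sd = params.sds[None, :]
    z = (y - mu) / sd
    with np.errstate(over="ignore"):
        ld = -0.5 * z * z - _LOG_SQRT_2PI - np.log(sd)
    if params.censored_last:
        at_s = values == params.S
        if at_s.any():
            k = params.K - 1
            a = (params.S - params.means[k]) / params.sds[k]
            ld[at_s, k] = log_ndtr(-a)
    with np.errstate(divide="ignore"):
        return ld + np.log(params.weights)[None, :]


def mixture_density(y, params: MixtureParams):
    """Mixture density f(y; theta); a mixed density/mass when censored_last."""
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if params.censored_last and np.any(y_arr > params.S):
        raise ValueError("observed value above the censoring threshold S")
    ld = _component_logdens(y_arr, params)
    out = np.exp(logsumexp(ld, axis=1))
    return float(out[0]) if np.isscalar(y) or np.ndim(y) == 0 else out


_DEFAULT_START_WEIGHTS = {1: (1.0,), 2: (0.8, 0.2), 3: (0.7, 0.1, 0.2)}


def initialize(mask: PixelMask, K: int, start_weights=None) -> MixtureParams:
    """Initial parameters from contiguous blocks of the sorted pixel values.

    The sorted values are partitioned into K blocks whose sizes are
    proportional to ``start_weights`` (defaults: 0.8/0.2 for K=2 and
    0.7/0.1/0.2 for K=3, matching typical background/intermediate/foreground
    shares of a target mask).  Block means and SDs seed mu and sigma;
    ``start_weights`` seed pi.
    """
    if K not in (1, 2, 3):
        raise ValueError("K must be in {1, 2, 3}")
    if mask.n < 3 * K:
        raise ValueError(f"need at least {3 * K} pixels to initialize K={K}")
    if start_weights is None:
        start_weights = _DEFAULT_START_WEIGHTS[K]
    w = np.asarray(start_weights, dtype=float)
    if w.size != K or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("start_weights must have length K and sum to 1")

    floor = _sigma_floor(mask.S, mask.values)
    srt = np.sort(mask.values)
    edges = np.round(np.cumsum(w) * mask.n).astype(int)
    edges[-1] = mask.n
    # every block must keep at least one pixel
    lo = 0
    bounds = []
    for j, hi in enumerate(edges):
        hi = max(hi, lo + 1)
        hi = min(hi, mask.n - (K - 1 - j))
        bounds.append((lo, hi))
        lo = hi

    means, sds = [], []
    for lo, hi in bounds:
        block = srt[lo:hi]
        means.append(float(block.mean()))
        sds.append(max(float(block.std()), floor))
    means = np.asarray(means)
    # enforce strict ordering for degenerate (e.g. constant) inputs
    eps = max(1e-9 * max(abs(means[-1]), 1.0), 1e-12)
    for k in range(1, K):
        if means[k] <= means[k - 1]:
            means[k] = means[k - 1] + eps
    return MixtureParams(w / w.sum(), means, np.asarray(sds),
                         censored_last=False, S=mask.S)


def e_step(mask: PixelMask, params: MixtureParams) -> np.ndarray:
    """Responsibilities z_ik = pi_k f_k(y_i) / f(y_i), computed in log space."""
    ld = _component_logdens(mask.values, params)
    norm = logsumexp(ld, axis=1)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("mixture density underflowed to 0 for some pixel")
    return np.exp(ld - norm[:, None])


def m_step(mask: PixelMask, resp: np.ndarray, censored_last: bool,
           prev: MixtureParams | None = None) -> tuple[MixtureParams, bool]:
    """Maximize the complete-data likelihood given responsibilities.

    Closed forms for every uncensored component; the censored last component
    is refit with the weighted censored-normal Newton solver (warm-started
    from ``prev``).  Components are re-sorted by mean afterwards.  Returns the
    new parameters and a degenerate-foreground flag (set when all the
    censored component's mass sits on saturated pixels).
    """
    y = mask.values
    n, K = resp.shape
    col = resp.sum(axis=0)
    bad = np.where(col < 1e-8 * n)[0]
    if bad.size:
        raise ComponentCollapseError(int(bad[0]))

    floor = _sigma_floor(mask.S, y)
    weights = col / n
    means = np.empty(K)
    sds = np.empty(K)
    for k in range(K):
        means[k] = float(resp[:, k] @ y / col[k])
        var = float(resp[:, k] @ (y - means[k]) ** 2 / col[k])
        sds[k] = max(math.sqrt(var), floor)

    degenerate = False
    if censored_last:
        k = K - 1
        init = None
        if prev is not None:
            init = CensoredNormalParams(float(prev.means[k]),
                                        max(float(prev.sds[k]), floor), mask.S)
        try:
            cn = fit_censored_normal(y, resp[:, k], mask.S, init=init,
                                     sigma_floor=floor, max_iter=50)
            means[k], sds[k] = cn.mu, cn.sigma
        except NonIdentifiableError:
            # all foreground mass saturated: pin the component at S
            means[k], sds[k] = mask.S, floor
            degenerate = True

    order = np.argsort(means, kind="stable")
    weights, means, sds = weights[order], means[order], sds[order]
    eps = max(1e-9 * max(abs(means[-1]), 1.0), 1e-12)
    for k in range(1, K):
        if means[k] <= means[k - 1]:
            means[k] = means[k - 1] + eps
    params = MixtureParams(weights / weights.sum(), means, sds,
                           censored_last=censored_last, S=mask.S)
    return params, degenerate


def _fit_k1(mask: PixelMask, censored: bool, floor: float) -> FitResult:
    y = mask.values
    use_censored = censored and np.isfinite(mask.S) and mask.n_saturated > 0
    if use_censored:
        cn, ok = fit_censored_normal(y, np.ones(mask.n), mask.S,
                                     sigma_floor=floor, full_output=True)
        mu, sd = cn.mu, cn.sigma
    else:
        mu = float(y.mean())
        sd = max(float(y.std()), floor)
        ok = True
    params = MixtureParams(np.array([1.0]), np.array([mu]), np.array([sd]),
                           censored_last=use_censored, S=mask.S)
    ll = float(logsumexp(_component_logdens(y, params), axis=1).sum())
    return FitResult(mask=mask, params=params, resp=np.ones((mask.n, 1)),
                     loglik=ll, loglik_trace=[ll], n_iter=0, converged=ok)


def fit_mixture(mask: PixelMask, K: int, censored: bool, *,
                tol: float = 1e-6, max_iter: int = 500,
                start_weights=None) -> FitResult:
    """EM fit of a K-component mixture to one target mask.

    ``censored`` selects the censored likelihood for the last component
    (saturated pixels contribute survival mass).  Iterates until the relative
    log-likelihood increase falls below ``tol`` or ``max_iter`` is reached;
    K=1 is fitted in closed form (or by the censored-normal solver when
    saturated pixels are present).
    """
    if K not in (1, 2, 3):
        raise ValueError("K must be in {1, 2, 3}")
    floor = _sigma_floor(mask.S, mask.values)
    if K == 1:
        return _fit_k1(mask, censored, floor)

    censored_last = censored and np.isfinite(mask.S)
    params = initialize(mask, K, start_weights)
    if censored_last:
        params = MixtureParams(params.weights, params.means, params.sds,
                               censored_last=True, S=mask.S)

    trace: list[float] = []
    degenerate = False
    converged = False
    prev_ll = -math.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ld = _component_logdens(mask.values, params)
        norm = logsumexp(ld, axis=1)
        if not np.all(np.isfinite(norm)):
            raise FloatingPointError("mixture density underflowed to 0")
        ll = float(norm.sum())
        if trace and ll < trace[-1] - 1e-8 * abs(trace[-1]):
            # the M-step re-sort moved the censored role to a different
            # component, changing the likelihood's meaning; EM restarts its
            # monotone ascent under the new labeling
            trace = [ll]
            prev_ll = -math.inf
        else:
            trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        resp = np.exp(ld - norm[:, None])
        params, degenerate = m_step(mask, resp, censored_last, prev=params)

    ld = _component_logdens(mask.values, params)
    norm = logsumexp(ld, axis=1)
    ll = float(norm.sum())
    resp = np.exp(ld - norm[:, None])
    if trace and ll > trace[-1] + 1e-12 * max(1.0, abs(ll)):
        trace.append(ll)

    # a component pinned at the scale floor away from the saturation pile-up
    # is a spurious singularity (it collapsed onto a handful of identical
    # pixels), not a cluster; reject the fit.  A floored component sitting at
    # S is kept: that is the regular model's point-mass response to saturated
    # ties, and the censored component may be legitimately pinned there too.
    for k in range(K):
        at_floor = params.sds[k] <= floor * (1 + 1e-9)
        at_ceiling = (np.isfinite(mask.S)
                      and abs(params.means[k] - mask.S) < 1e-6 * abs(mask.S))
        if at_floor and not at_ceiling:
            raise ComponentCollapseError(k)
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations "
                      f"(spot {mask.spot_id}, K={K})", RuntimeWarning,
                      stacklevel=2)
    return FitResult(mask=mask, params=params, resp=resp, loglik=ll,
                     loglik_trace=trace, n_iter=n_iter, converged=converged,
                     degenerate_fg=degenerate)


def _pick_by_relative_rule(crits: dict[int, float], rel_threshold: float) -> int:
    """Smallest K whose criterion is within ``rel_threshold`` (relative) of the best."""
    best = min(crits.values())
    denom = abs(best)
    for K in sorted(crits):
        excess = crits[K] - best
        if denom == 0 or excess / denom < rel_threshold:
            return K
    return min(crits, key=crits.get)  # pragma: no cover


def select_K(mask: PixelMask, censored: bool, criterion: str = "bic",
             rel_threshold: float = 0.001, Kmax: int = 3, *,
             tol: float = 1e-6, max_iter: int = 500) -> FitResult:
    """Fit K = 1..Kmax and select by AIC/BIC with the relative-difference rule.

    Among the fitted models, the smallest K whose criterion exceeds the best
    one by less than ``rel_threshold`` (relative) is preferred — a simpler
    model within 0.1% of the best is taken over a more complex one.  A K=1
    winner marks the spot as blank/weak.
    """
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    fits: dict[int, FitResult] = {}
    for K in range(1, Kmax + 1):
        if K > 1 and mask.n < 3 * K:
            continue
        try:
            fits[K] = fit_mixture(mask, K, censored, tol=tol, max_iter=max_iter)
        except (ComponentCollapseError, NonIdentifiableError, FloatingPointError) as exc:
            warnings.warn(f"K={K} fit failed for spot {mask.spot_id}: {exc}",
                          RuntimeWarning, stacklevel=2)
    if not fits:
        raise RuntimeError(f"all mixture fits failed for spot {mask.spot_id}")
    crits = {K: getattr(f, criterion) for K, f in fits.items()}
    return fits[_pick_by_relative_rule(crits, rel_threshold)]
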