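"""Univariate normal distribution right-censored at a known threshold.

A scanner records pixel intensities only up to its saturation ceiling ``S``
(65535 for 16-bit images); any pixel whose true brightness exceeds ``S`` is
recorded as exactly ``S``.  Statistically such a pixel is a right-censored
observation: it contributes the survival probability ``1 - Phi((S-mu)/sigma)``
to the likelihood instead of a density value.  This module provides the
density, the weighted log-likelihood and the weighted maximum-likelihood fit
for this censored normal — the building block for the censored component of
the pixel mixture model.

The MLE has no closed form once censored observations are present, so the fit
uses Newton-Raphson with analytic gradient and Hessian in the parametrisation
``(mu, log sigma)`` (keeping ``sigma > 0`` without projection), with step
halving to guarantee likelihood ascent and a derivative-free Nelder-Mead
fallback if the Hessian is unusable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr

__all__ = [
    "CensoredNormalParams",
    "NonIdentifiableError",
    "censored_density",
    "censored_loglik",
    "fit_censored_normal",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Default scale floor as a fraction of the censoring threshold; prevents a
#: degenerate point mass at S when nearly all mass sits on saturated pixels.
SIGMA_FLOOR_FRAC = 1e-6


class NonIdentifiableError(ValueError):
    """All weighted mass lies on censored observations.

    The censored-normal likelihood then increases without bound in ``mu``
    (pushing the whole distribution above the threshold), so no maximum
    exists.
    """


@dataclass(frozen=True)
class CensoredNormalParams:
    """Location/scale of a normal right-censored at ``S`` (intensity units)."""

    mu: float
    sigma: float
    S: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not np.isfinite(self.S):
            raise ValueError("censoring threshold S must be finite")


def _norm_logpdf(z: np.ndarray) -> np.ndarray:
    return -0.5 * z * z - _LOG_SQRT_2PI


def _logsf(a: float) -> float:
    """log(1 - Phi(a)), numerically stable far into the tail."""
    return float(log_ndtr(-a))


def censored_density(y, p: CensoredNormalParams):
    """Mixed density of the censored normal at ``y``.

    Returns the normal pdf for ``y < S`` and the point mass
    ``1 - Phi((S - mu)/sigma)`` for ``y == S`` (density with respect to
    Lebesgue measure plus an atom at ``S``).  Values above ``S`` cannot be
    observed and raise ``ValueError``.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr > p.S):
        raise ValueError("observed value above the censoring threshold S")
    z = (y_arr - p.mu) / p.sigma
    pdf = np.exp(_norm_logpdf(z)) / p.sigma
    mass = math.exp(_logsf((p.S - p.mu) / p.sigma))
    out = np.where(y_arr == p.S, mass, pdf)
    return float(out) if np.isscalar(y) or out.ndim == 0 else out


def censored_loglik(y, w, p: CensoredNormalParams) -> float:
    """Weighted log-likelihood ``sum_i w_i log f(y_i)`` under the censored normal.

    Terms with zero weight contribute nothing even if their log-density is
    ``-inf``; the result may be ``-inf`` when a positively-weighted term has
    zero density.
    """
    y_arr = np.asarray(y, dtype=float)
    w_arr = np.asarray(w, dtype=float)
    if y_arr.shape != w_arr.shape:
        raise ValueError("y and w must have the same length")
    if np.any(w_arr < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(y_arr > p.S):
        raise ValueError("observed value above the censoring threshold S")

    cens = y_arr == p.S
    pos = w_arr > 0
    total = 0.0
    m_unc = pos & ~cens
    if m_unc.any():
        z = (y_arr[m_unc] - p.mu) / p.sigma
        total += float(np.sum(w_arr[m_unc] * (_norm_logpdf(z) - math.log(p.sigma))))
    m_cen = pos & cens
    if m_cen.any():
        total += float(np.sum(w_arr[m_cen])) * _logsf((p.S - p.mu) / p.sigma)
    return total


def _weighted_mle_uncensored(y: np.ndarray, w: np.ndarray, floor: float) -> tuple[float, float]:
    wt = w.sum()
    mu = float(np.sum(w * y) / wt)
    var = float(np.sum(w * (y - mu) ** 2) / wt)
    return mu, max(math.sqrt(var), floor)


def _grad_hess(mu: float, eta: float, y_unc: np.ndarray, w_unc: np.ndarray,
               wc: float, S: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood, gradient and Hessian in (mu, eta=log sigma)."""
    sigma = math.exp(eta)
    z = (y_unc - mu) / sigma
    sw = float(w_unc.sum())
    swz = float(np.sum(w_unc * z))
    swz2 = float(np.sum(w_unc * z * z))

    ll = float(np.sum(w_unc * (_norm_logpdf(z) - eta)))
    g_mu = swz / sigma
    g_eta = swz2 - sw
    h_mm = -sw / sigma**2
    h_me = -2.0 * swz / sigma
    h_ee = -2.0 * swz2

    if wc > 0:
        a = (S - mu) / sigma
        lsf = _logsf(a)
        ll += wc * lsf
        lam = math.exp(_norm_logpdf(np.array(a)) - lsf)  # hazard phi/ (1-Phi)
        dlam = lam * (lam - a)
        g_mu += wc * lam / sigma
        g_eta += wc * lam * a
        h_mm += -wc * dlam / sigma**2
        h_me += -wc * (a * dlam + lam) / sigma
        h_ee += -wc * a * (a * dlam + lam)

    grad = np.array([g_mu, g_eta])
    hess = np.array([[h_mm, h_me], [h_me, h_ee]])
    return ll, grad, hess


def fit_censored_normal(y, w, S: float, init: CensoredNormalParams | None = None,
                        *, tol: float = 1e-8, max_iter: int = 100,
                        sigma_floor: float | None = None,
                        full_output: bool = False):
    """Weighted ML fit of a normal right-censored at ``S``.

    Parameters
    ----------
    y, w
        Observations (all ``<= S``; values exactly equal to ``S`` are treated
        as censored) and their nonnegative weights.
    init
        Warm start; defaults to weighted moments of the data (censored values
        entering at ``S``).
    full_output
        When true, also return a ``converged`` flag.

    Raises
    ------
    NonIdentifiableError
        If no uncensored observation carries positive weight.
    """
    y_arr = np.asarray(y, dtype=float)
    w_arr = np.asarray(w, dtype=float)
    if y_arr.shape != w_arr.shape:
        raise ValueError("y and w must have the same length")
    if np.any(w_arr < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(y_arr > S):
        raise ValueError("observed value above the censoring threshold S")

    if sigma_floor is None:
        sigma_floor = SIGMA_FLOOR_FRAC * abs(S) if np.isfinite(S) else 1e-6
    eta_floor = math.log(sigma_floor)

    cens = y_arr == S
    y_unc, w_unc = y_arr[~cens], w_arr[~cens]
    wc = float(w_arr[cens].sum())
    if float(w_unc.sum()) <= 0:
        raise NonIdentifiableError(
            "all weighted mass lies on censored observations; mu is not identifiable"
        )

    if wc == 0:
        mu, sigma = _weighted_mle_uncensored(y_unc, w_unc, sigma_floor)
        params = CensoredNormalParams(mu, sigma, S)
        return (params, True) if full_output else params

    if init is not None:
        mu, sigma = float(init.mu), max(float(init.sigma), sigma_floor)
    else:
        mu, sigma = _weighted_mle_uncensored(y_arr, w_arr, sigma_floor)
    eta = math.log(sigma)

    def _grad_small(grad: np.ndarray, sigma: float, sw_total: float) -> bool:
        # gradient in natural (per-sigma) scale, relative to the weight mass
        return max(abs(grad[0]) * sigma, abs(grad[1])) < 1e-6 * max(1.0, sw_total)

    def _polish(mu: float, eta: float) -> tuple[float, float, float, bool]:
        res = minimize(
            lambda x: -_grad_hess(x[0], max(x[1], eta_floor), y_unc, w_unc, wc, S)[0],
            np.array([mu, eta]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        mu, eta = float(res.x[0]), max(float(res.x[1]), eta_floor)
        return mu, eta, float(-res.fun), bool(res.success)

    sw_total = float(w_arr.sum())
    ll, grad, hess = _grad_hess(mu, eta, y_unc, w_unc, wc, S)
    converged = False
    for _ in range(max_iter):
        if _grad_small(grad, math.exp(eta), sw_total):
            converged = True
            break
        stalled = not (np.all(np.isfinite(grad)) and np.all(np.isfinite(hess)))
        step = None
        if not stalled:
            # Levenberg-modified Newton: shift the Hessian until the step is
            # finite and points uphill (handles indefinite Hessians with the
            # right scaling in each coordinate)
            lam = 0.0
            scale = float(np.abs(hess).max()) or 1.0
            for _ in range(60):
                try:
                    cand = np.linalg.solve(hess - lam * np.eye(2), -grad)
                except np.linalg.LinAlgError:
                    cand = None
                if (cand is not None and np.all(np.isfinite(cand))
                        and float(cand @ grad) > 0):
                    step = cand
                    break
                lam = scale * 1e-6 if lam == 0.0 else lam * 10.0
            stalled = step is None
        if not stalled:
            t = 1.0
            ll_new = -math.inf
            for _ in range(40):
                mu_new = mu + t * step[0]
                eta_new = max(eta + t * step[1], eta_floor)
                ll_new = _grad_hess(mu_new, eta_new, y_unc, w_unc, wc, S)[0]
                if np.isfinite(ll_new) and ll_new > ll:
                    break
                t *= 0.5
            else:
                stalled = True
        if stalled:
            mu, eta, ll, converged = _polish(mu, eta)
            break
        delta = ll_new - ll
        mu, eta = mu_new, eta_new
        ll, grad, hess = _grad_hess(mu, eta, y_unc, w_unc, wc, S)
        if abs(delta) < tol and _grad_small(grad, math.exp(eta), sw_total):
            converged = True
            break

    if not converged and not _grad_small(grad, math.exp(eta), sw_total):
        mu, eta, ll, converged = _polish(mu, eta)
    if not converged:
        warnings.warn("censored-normal fit did not converge", RuntimeWarning,
                      stacklevel=2)
    params = CensoredNormalParams(mu, math.exp(max(eta, eta_floor)), S)
    return (params, converged) if full_output else params
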