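"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's own numerical kernels: the
censored-normal reference log-likelihood is evaluated through scipy.stats and
maximized by brute-force grid refinement, and mask assignment is rechecked by
a naive nearest-center scan.  Package results are compared against these
independent routes.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import norm


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def censored_loglik_ref(y, w, mu, sigma, S):
    """Reference weighted censored-normal log-likelihood via scipy.stats."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    cens = y == S
    ll = float(np.sum(w[~cens] * norm.logpdf(y[~cens], mu, sigma)))
    if cens.any():
        ll += float(np.sum(w[cens])) * float(norm.logsf(S, mu, sigma))
    return ll


def grid_search_censored_mle(y, w, S, mu_range, sigma_range, n_grid=60, rounds=5):
    """Brute-force MLE by iteratively refined (mu, sigma) grid search.

    Returns (mu, sigma, final grid resolution in each coordinate).
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    cens = y == S
    mu_lo, mu_hi = mu_range
    sg_lo, sg_hi = sigma_range
    best = (None, None)
    for _ in range(rounds):
        mus = np.linspace(mu_lo, mu_hi, n_grid)
        sgs = np.linspace(max(sg_lo, 1e-3), sg_hi, n_grid)
        mu_b = mus[:, None, None]
        sg_b = sgs[None, :, None]
        ll = np.sum(w[~cens] * norm.logpdf(y[~cens], mu_b, sg_b), axis=-1)
        if cens.any():
            ll = ll + w[cens].sum() * norm.logsf(S, mus[:, None], sgs[None, :])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(mus[i]), float(sgs[j]))
        dmu = mus[1] - mus[0]
        dsg = sgs[1] - sgs[0]
        mu_lo, mu_hi = best[0] - 2 * dmu, best[0] + 2 * dmu
        sg_lo, sg_hi = best[1] - 2 * dsg, best[1] + 2 * dsg
    return best[0], best[1], (dmu, dsg)


def brute_force_assignment(centers, pitch, image_shape):
    """Naive per-pixel nearest-center scan; -1 where no center within pitch."""
    rows, cols = image_shape
    out = np.full((rows, cols), -1, dtype=int)
    centers = np.asarray(centers, float)
    for r in range(rows):
        for c in range(cols):
            d = np.hypot(centers[:, 0] - c, centers[:, 1] - r)
            k = int(np.argmin(d))
            if d[k] <= pitch:
                out[r, c] = k
    return out
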