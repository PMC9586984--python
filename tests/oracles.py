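"""Independent oracles: dense grid search MLE and erf-based normal CDF.

These deliberately avoid the code paths of the implementation (Newton
iterations, scipy's ndtr/ndtri) so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def normal_cdf_erf(z: float) -> float:
    """Standard-normal CDF via the error function."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def normal_quantile_erf(p: float) -> float:
    """Standard-normal quantile by root-finding on the erf-based CDF."""
    return brentq(lambda z: normal_cdf_erf(z) - p, -40.0, 40.0, xtol=1e-14)


def _aggregate(x, y):
    scores = np.unique(x)
    n_s = np.array([(x == s).sum() for s in scores], dtype=float)
    pos_s = np.array([y[x == s].sum() for s in scores], dtype=float)
    return scores, n_s, pos_s


def grid_loglik_max(
    x,
    y,
    b0_range=(-5.0, 5.0),
    b1_range=(-1.0, 1.0),
    n_grid=201,
):
    """Best clipped probit log-likelihood over a dense (b0, b1) grid.

    The likelihood only depends on (x, y) through per-score counts, so the
    201x201 grid costs n_grid^2 * n_distinct_scores CDF evaluations.
    Returns (best loglik, (b0, b1) at the best grid point).
    """
    from scipy.special import ndtr

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scores, n_s, pos_s = _aggregate(x, y)
    b0s = np.linspace(*b0_range, n_grid)
    b1s = np.linspace(*b1_range, n_grid)
    eta = b0s[:, None, None] + b1s[None, :, None] * scores[None, None, :]
    p = np.clip(ndtr(eta), 1e-15, 1.0 - 1e-15)
    ll = (pos_s * np.log(p) + (n_s - pos_s) * np.log(1.0 - p)).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(ll[i, j]), (float(b0s[i]), float(b1s[j]))


def brute_force_tune(models, target_detected: int, grid_step: float = 0.1):
    """Exhaustive scan reimplementation of the level-tuning criterion.

    ``models``: iterables of (beta0, beta1, ais array, y array).  Counts the
    detected positives per level by explicit boolean masks (no sorting or
    suffix-sum tricks) and applies argmin |detected-target| with the
    larger-level tie-break.
    """
    best_q, best_diff = None, None
    q = grid_step
    while q <= 100.0 - grid_step + 1e-9:
        detected = 0
        for beta0, beta1, ais, y in models:
            cutoff = (normal_quantile_erf(q / 100.0) - beta0) / beta1
            detected += int(y[ais >= cutoff].sum())
        diff = abs(detected - target_detected)
        if best_diff is None or diff <= best_diff:
            best_q, best_diff = q, diff
        q = round(q + grid_step, 10)
    return best_q
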