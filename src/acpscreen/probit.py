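"""Single-predictor probit regression and ACP (cutoff) inversion.

The screening model is a Bernoulli GLM with a probit link fitted separately
within each risk stratum:

    P(positive | score = x) = Phi(beta0 + beta1 * x)

where ``Phi`` is the standard-normal CDF, the outcome is binarized CES-D
(depressive symptoms) and the score is the Athens Insomnia Scale (AIS,
integers 0..24).  The quantity of interest is the inverse of the fitted
curve: ACPq, the AIS value at which the estimated prevalence equals q, i.e.

    ACPq = (Phi^-1(q) - beta0) / beta1          (ACP50 = -beta0/beta1)

which plays the same role as an ED50 read off a dose-response curve.

The likelihood is maximized by Newton-Raphson on (beta0, beta1).  For the
probit log-likelihood the negative observed Hessian is positive definite
wherever the parameters are finite, so full Newton steps (with step halving
as a safeguard) are used throughout; standard errors come from the inverse
observed information at the optimum and inference is Wald/normal, matching
conventional glm output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

from .errors import (
    IdentifiabilityError,
    InsufficientDataError,
    NonInvertibleError,
    NotConvergedError,
    NoVariationError,
)

__all__ = [
    "ProbitFit",
    "ACP",
    "fit_probit",
    "predict_prevalence",
    "acp",
    "wald_inference",
    "score_prevalence_table",
    "estimated_vs_observed",
    "probit_loglik",
    "Z_975",
]

# Conventional two-sided 95% normal quantile, fixed to keep table output stable.
Z_975 = 1.959963985

_CLIP = 1e-15          # probability clip inside the likelihood
_MAX_ABS_BETA = 50.0   # beyond this the data are (quasi-)separated
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ProbitFit:
    """Maximum-likelihood fit of ``P(y=1|x) = Phi(beta0 + beta1*x)``."""

    beta0: float
    beta1: float
    se0: float
    se1: float
    p0: float
    p1: float
    ci0: tuple[float, float]
    ci1: tuple[float, float]
    n: int
    n_pos: int
    loglik: float
    converged: bool
    n_iter: int
    separated: bool = False
    inference_available: bool = True


@dataclass(frozen=True)
class ACP:
    """AIS value at which the fitted prevalence equals ``level``.

    ``ais_value`` may fall outside the instrument's 0..24 range (the curve is
    defined on the whole line); ``in_range`` records whether it is usable as a
    literal questionnaire cutoff.
    """

    level: float
    ais_value: float
    in_range: bool


def probit_loglik(beta0: float, beta1: float, x: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood with probabilities clipped to [1e-15, 1-1e-15]."""
    p = np.clip(ndtr(beta0 + beta1 * np.asarray(x, dtype=float)), _CLIP, 1.0 - _CLIP)
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _score_and_neg_hessian(params, x, y):
    """Gradient and negative Hessian of the probit log-likelihood.

    Uses the sign trick q = 2y-1: each observation contributes log Phi(q*eta).
    With m = phi(z)/Phi(z) evaluated at z = q*eta (computed on the log scale so
    extreme z stay finite), the score is X'(q*m) and the negative Hessian is
    X' diag(m*(m+z)) X, which is positive definite for finite parameters.
    """
    eta = params[0] + params[1] * x
    q = 2.0 * y - 1.0
    z = q * eta
    m = np.exp(-0.5 * z * z - 0.5 * _LOG_2PI - log_ndtr(z))
    w = m * (m + z)
    g0 = np.sum(q * m)
    g1 = np.sum(q * m * x)
    h00 = np.sum(w)
    h01 = np.sum(w * x)
    h11 = np.sum(w * x * x)
    return np.array([g0, g1]), np.array([[h00, h01], [h01, h11]])


def fit_probit(
    x,
    y,
    *,
    max_iter: int = 100,
    tol_loglik: float = 1e-10,
    tol_grad: float = 1e-8,
) -> ProbitFit:
    """Fit the probit model of binary ``y`` on score ``x`` by Newton-Raphson.

    Convergence requires both a log-likelihood change below ``tol_loglik`` and
    a gradient max-norm below ``tol_grad``.  When any coefficient exceeds 50 in
    absolute value the data are treated as separated and the fit is returned
    with ``converged=False, separated=True`` (models that "cannot be
    constructed" in registry terms).

    Raises
    ------
    NoVariationError
        ``y`` is all 0 or all 1.
    IdentifiabilityError
        ``x`` is constant, so the slope is not identifiable.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"x and y have different lengths ({x.size} vs {y.size})")
    if x.size < 2:
        raise ValueError("at least 2 observations are required")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("y must be binary 0/1")
    n = int(x.size)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == n:
        raise NoVariationError(f"outcome has no variation ({n_pos} positives of {n})")
    if np.ptp(x) == 0.0:
        raise IdentifiabilityError("x is constant; slope is not identifiable")

    # Start at the intercept-only MLE.
    params = np.array([ndtri(n_pos / n), 0.0])
    ll = probit_loglik(params[0], params[1], x, y)
    converged = False
    separated = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        grad, neg_hess = _score_and_neg_hessian(params, x, y)
        try:
            step = np.linalg.solve(neg_hess, grad)
        except np.linalg.LinAlgError:
            break
        # Step halving: the Newton direction is an ascent direction here, so
        # some fraction of it improves the (clipped) log-likelihood.
        scale = 1.0
        for _ in range(40):
            trial = params + scale * step
            ll_trial = probit_loglik(trial[0], trial[1], x, y)
            if ll_trial >= ll - 1e-13:
                break
            scale *= 0.5
        params = params + scale * step
        delta_ll = ll_trial - ll
        ll = ll_trial
        if np.max(np.abs(params)) > _MAX_ABS_BETA:
            separated = True
            break
        grad_new, _ = _score_and_neg_hessian(params, x, y)
        if abs(delta_ll) < tol_loglik and np.max(np.abs(grad_new)) < tol_grad:
            converged = True
            break

    _, neg_hess = _score_and_neg_hessian(params, x, y)
    se = np.array([np.nan, np.nan])
    inference_available = False
    if converged:
        try:
            cov = np.linalg.inv(neg_hess)
            diag = np.diag(cov)
            if np.all(diag > 0):
                se = np.sqrt(diag)
                inference_available = True
        except np.linalg.LinAlgError:
            pass

    fit = ProbitFit(
        beta0=float(params[0]),
        beta1=float(params[1]),
        se0=float(se[0]),
        se1=float(se[1]),
        p0=np.nan,
        p1=np.nan,
        ci0=(np.nan, np.nan),
        ci1=(np.nan, np.nan),
        n=n,
        n_pos=n_pos,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        separated=separated,
        inference_available=inference_available,
    )
    return wald_inference(fit) if inference_available else fit


def wald_inference(fit: ProbitFit) -> ProbitFit:
    """Attach two-sided Wald p-values and 95% CIs computed from the SEs.

    ``p_k = 2*(1 - Phi(|beta_k|/se_k))`` and ``CI = beta_k +/- z_0.975*se_k``.
    If the information matrix was singular (``inference_available=False``) the
    fit is returned unchanged with NaN inference fields.
    """
    if not fit.inference_available:
        return fit
    p0 = float(2.0 * (1.0 - ndtr(abs(fit.beta0) / fit.se0))) if fit.se0 > 0 else 0.0
    p1 = float(2.0 * (1.0 - ndtr(abs(fit.beta1) / fit.se1))) if fit.se1 > 0 else 0.0
    return dataclasses.replace(
        fit,
        p0=p0,
        p1=p1,
        ci0=(fit.beta0 - Z_975 * fit.se0, fit.beta0 + Z_975 * fit.se0),
        ci1=(fit.beta1 - Z_975 * fit.se1, fit.beta1 + Z_975 * fit.se1),
    )


def predict_prevalence(fit: ProbitFit, x):
    """Estimated prevalence ``Phi(beta0 + beta1*x)`` at score(s) ``x``."""
    if not fit.converged:
        raise NotConvergedError("prediction requires a converged fit")
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValueError("x must be finite")
    out = ndtr(fit.beta0 + fit.beta1 * x_arr)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def acp(fit: ProbitFit, level: float) -> ACP:
    """Invert the fitted curve: the AIS value with estimated prevalence ``level``.

    ``ais_value = (Phi^-1(level) - beta0)/beta1``; for level 0.5 this is the
    classical -beta0/beta1.  The value may land outside [0, 24]; ``in_range``
    says whether it does not.
    """
    if not fit.converged:
        raise NotConvergedError("ACP requires a converged fit")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0,1), got {level}")
    if abs(fit.beta1) < 1e-12:
        raise NonInvertibleError("slope is numerically zero; curve not invertible")
    ais_value = (ndtri(level) - fit.beta0) / fit.beta1
    return ACP(level=float(level), ais_value=float(ais_value), in_range=bool(0.0 <= ais_value <= 24.0))


def score_prevalence_table(fit: ProbitFit, x, y):
    """Per-AIS-score counts with observed and model-estimated prevalence.

    Returns a DataFrame over scores 0..24 with columns ``n``, ``n_pos``,
    ``observed`` (NaN where n=0) and ``estimated`` (= Phi(beta0+beta1*s)).
    """
    import pandas as pd

    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    scores = np.arange(25)
    n_s = np.array([(x == s).sum() for s in scores])
    pos_s = np.array([y[x == s].sum() for s in scores])
    with np.errstate(invalid="ignore"):
        observed = np.where(n_s > 0, pos_s / np.maximum(n_s, 1), np.nan)
    estimated = ndtr(fit.beta0 + fit.beta1 * scores.astype(float))
    return pd.DataFrame(
        {"score": scores, "n": n_s, "n_pos": pos_s.astype(int), "observed": observed, "estimated": estimated}
    )


def estimated_vs_observed(fit: ProbitFit, x, y):
    """Validate a fit: Pearson r between observed and estimated prevalence.

    The correlation is taken over the AIS scores that are actually populated
    (n(s) > 0); at least 3 populated scores are required.
    """
    table = score_prevalence_table(fit, x, y)
    populated = table["n"] > 0
    if int(populated.sum()) < 3:
        raise InsufficientDataError("fewer than 3 populated AIS scores")
    obs = table.loc[populated, "observed"].to_numpy()
    est = table.loc[populated, "estimated"].to_numpy()
    r = float(np.corrcoef(obs, est)[0, 1])
    return table, r
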