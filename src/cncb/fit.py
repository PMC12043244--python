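"""Maximum-likelihood fitting of the confidence model to rating counts.

The multinomial log-likelihood of a count tensor n[i, j, k] under the
model probabilities P(j, k | i) is

    L = sum_{i,j,k} n_{i,j,k} log P(j,k|i),

maximized over (sigma_s, theta_s, sigma_c, alpha, b_1..b_{m-1}); one set
of sensory parameters explains the perceptual responses and the
confidence judgments jointly.  Goodness of fit is the deviance
G^2 = -2 (L - Ls) against the saturated model Ls (empirical
frequencies).  The optimizer works on an unconstrained transform of the
parameters (logs for scales, logit for the boost, first boundary plus
log-increments for the ordered boundaries), with a derivative-free
simplex stage refined by a quasi-Newton polish, from several starting
points to avoid local maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtri
from scipy.stats import chi2

from .data import RatingCounts
from .model import ConfidenceParams, SensoryParams, response_probabilities
from .simulate import calibrate_boundaries
from .exceptions import CalibrationError

__all__ = [
    "FitResult",
    "log_likelihood",
    "saturated_log_likelihood",
    "fit_cncb",
    "lr_test",
]

_P_FLOOR = 1e-12       # probability floor inside the log
_SIGMA_C_MIN = 1e-4    # lower bound for confidence noise during fitting
_LOGIT_CLIP = 13.0     # |logit(alpha)| bound; alpha may cling to 0/1


def log_likelihood(sens: SensoryParams, conf: ConfidenceParams,
                   counts: RatingCounts) -> float:
    """Multinomial log-likelihood of the counts under the model.

    Zero-count cells contribute exactly 0; model probabilities are floored
    at 1e-12 before the log so boundary-calibration edge cells cannot
    produce -inf.
    """
    table = response_probabilities(sens, conf)
    n = counts.n
    p = np.maximum(table.p, _P_FLOOR)
    return float(np.sum(np.where(n > 0, n * np.log(p), 0.0)))


def saturated_log_likelihood(counts: RatingCounts) -> float:
    """Upper bound on the log-likelihood: the empirical frequencies used
    as the model (0-count terms are 0)."""
    n = counts.n.astype(float)
    tot = counts.totals[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * (np.log(n) - np.log(tot)), 0.0)
    return float(terms.sum())


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    sens: SensoryParams
    conf: ConfidenceParams
    logL: float
    logL_saturated: float
    deviance: float
    n_free_params: int
    converged: bool
    model_variant: str
    starts: tuple = ()
    counts: RatingCounts | None = None

    @property
    def df_residual(self) -> int:
        """Residual degrees of freedom of the deviance."""
        c = self.counts
        return c.n_stimuli * (2 * c.m - 1) - self.n_free_params


class _Objective:
    """Negative log-likelihood on the unconstrained parameter vector.

    Layout: [log sigma_s, theta_s,] log sigma_c, [logit alpha,] b_1,
    log(b_2 - b_1), ..., with the bracketed blocks dropped when the
    sensory parameters are fixed or the variant has no boost.
    """

    def __init__(self, counts: RatingCounts, with_boost: bool,
                 fix_sensory: tuple[float, float] | None):
        self.counts = counts
        self.with_boost = with_boost
        self.fix_sensory = fix_sensory
        self.m = counts.m

    def unpack(self, x: np.ndarray) -> tuple[SensoryParams, ConfidenceParams]:
        pos = 0
        if self.fix_sensory is None:
            sigma_s = float(np.exp(np.clip(x[0], -12, 12)))
            theta_s = float(x[1])
            pos = 2
        else:
            sigma_s, theta_s = self.fix_sensory
        sigma_c = float(np.exp(np.clip(x[pos], np.log(_SIGMA_C_MIN), 12)))
        pos += 1
        if self.with_boost:
            alpha = float(expit(np.clip(x[pos], -_LOGIT_CLIP, _LOGIT_CLIP)))
            pos += 1
        else:
            alpha = 0.0
        b1 = x[pos]
        incr = np.exp(np.clip(x[pos + 1:], -20, 20))
        bounds = np.concatenate([[b1], b1 + np.cumsum(incr)])
        sens = SensoryParams(mu=self.counts.mu, sigma_s=sigma_s, theta_s=theta_s)
        conf = ConfidenceParams(sigma_c=sigma_c, alpha=alpha, boundaries=bounds)
        return sens, conf

    def pack(self, sigma_s, theta_s, sigma_c, alpha, boundaries) -> np.ndarray:
        x = []
        if self.fix_sensory is None:
            x += [np.log(sigma_s), theta_s]
        x.append(np.log(max(sigma_c, _SIGMA_C_MIN)))
        if self.with_boost:
            x.append(float(logit(np.clip(alpha, 1e-5, 1 - 1e-5))))
        b = np.atleast_1d(np.asarray(boundaries, dtype=float))
        x.append(b[0])
        x += list(np.log(np.maximum(np.diff(b), 1e-8)))
        return np.asarray(x)

    def __call__(self, x: np.ndarray) -> float:
        try:
            sens, conf = self.unpack(x)
            return -log_likelihood(sens, conf, self.counts)
        except (ValueError, FloatingPointError):
            return 1e12


def _type1_start(counts: RatingCounts) -> tuple[float, float]:
    """Probit initialization of (sigma_s, theta_s) from Type 1 margins."""
    tot = counts.totals
    p_plus = counts.n[:, 1, :].sum(axis=1) / tot
    p_plus = np.clip(p_plus, 1.0 / (2 * tot.max()), 1 - 1.0 / (2 * tot.max()))
    z = ndtri(p_plus)
    slope, intercept = np.polyfit(counts.mu, z, 1)
    slope = max(slope, 1e-3)
    sigma_s = 1.0 / slope
    theta_s = -intercept * sigma_s
    return float(np.clip(sigma_s, 1e-3, 1e3)), float(np.clip(theta_s, -10, 10))


def _boundary_start(counts: RatingCounts, sens: SensoryParams,
                    sigma_c: float, alpha: float) -> np.ndarray:
    """Boundaries matching the empirical pooled rating marginals at the
    starting Type 2 parameters."""
    q = counts.n.sum(axis=(0, 1)).astype(float)
    q = np.maximum(q, 0.5)
    q /= q.sum()
    try:
        return calibrate_boundaries(sens, sigma_c, alpha, q)
    except CalibrationError:
        cum = np.cumsum(q)[:-1]
        return ndtri(np.clip(cum, 1e-6, 1 - 1e-6))


def fit_cncb(
    counts: RatingCounts,
    model_variant: str = "with_boost",
    fix_sensory: tuple[float, float] | None = None,
    options: dict | None = None,
) -> FitResult:
    """Fit the confidence model to a count tensor by maximum likelihood.

    Parameters
    ----------
    counts : RatingCounts
        Aggregated trial counts, >= 2 stimuli and >= 2 levels.
    model_variant : {'with_boost', 'no_boost'}
        'no_boost' fixes the confidence boost at 0 (one fewer parameter).
    fix_sensory : (sigma_s, theta_s), optional
        Hold the sensory parameters fixed instead of fitting them jointly.
    options : dict, optional
        ``tol`` (default 1e-8, log-likelihood tolerance), ``nm_maxiter``,
        ``polish`` (quasi-Newton refinement, default True), ``starts``
        (extra (sigma_c, alpha) starting pairs).

    Non-convergence in all starts is reported through ``converged=False``
    rather than an exception.
    """
    if model_variant not in ("with_boost", "no_boost"):
        raise ValueError("model_variant must be 'with_boost' or 'no_boost'")
    if counts.m < 2 or counts.n_stimuli < 2:
        raise ValueError("fitting needs >= 2 stimuli and >= 2 levels")
    opts = {"tol": 1e-8, "nm_maxiter": None, "polish": True, "starts": None}
    opts.update(options or {})
    with_boost = model_variant == "with_boost"

    obj = _Objective(counts, with_boost, fix_sensory)
    if fix_sensory is None:
        sig0, th0 = _type1_start(counts)
    else:
        sig0, th0 = fix_sensory
    sens0 = SensoryParams(mu=counts.mu, sigma_s=sig0, theta_s=th0)

    if opts["starts"] is not None:
        start_pairs = list(opts["starts"])
    elif with_boost:
        start_pairs = [(sc, a) for sc in (0.5, 2.0) for a in (0.25, 0.75)]
    else:
        start_pairs = [(0.5, 0.0), (2.0, 0.0)]

    best = None
    diagnostics = []
    for sc0, a0 in start_pairs:
        b0 = _boundary_start(counts, sens0, sc0, a0)
        x0 = obj.pack(sig0, th0, sc0, a0, b0)
        nm_maxiter = opts["nm_maxiter"] or 60 * x0.size
        res = minimize(
            obj, x0, method="Nelder-Mead",
            options={"maxiter": nm_maxiter, "fatol": max(opts["tol"], 1e-8),
                     "xatol": 1e-6, "adaptive": True},
        )
        diagnostics.append(
            {"sigma_c0": sc0, "alpha0": a0, "logL": -float(res.fun),
             "converged": bool(res.success), "n_eval": int(res.nfev)}
        )
        if best is None or res.fun < best.fun:
            best = res

    if opts["polish"]:
        # quasi-Newton refinement of the best simplex solution
        res2 = minimize(obj, best.x, method="L-BFGS-B",
                        options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 100})
        if res2.fun <= best.fun:
            best = res2
        diagnostics.append({"stage": "polish", "logL": -float(best.fun),
                            "converged": bool(best.success),
                            "n_eval": int(best.nfev)})

    sens, conf = obj.unpack(best.x)
    logl = -float(best.fun)
    ls = saturated_log_likelihood(counts)
    n_free = (0 if fix_sensory is not None else 2) + 1 + (1 if with_boost else 0) \
        + (counts.m - 1)
    return FitResult(
        sens=sens,
        conf=conf,
        logL=logl,
        logL_saturated=ls,
        deviance=max(0.0, -2.0 * (logl - ls)),
        n_free_params=n_free,
        converged=any(d["converged"] for d in diagnostics),
        model_variant=model_variant,
        starts=tuple(diagnostics),
        counts=counts,
    )


def lr_test(fit_no_boost: FitResult, fit_with_boost: FitResult) -> tuple[float, float]:
    """Likelihood-ratio test of the boost parameter between nested fits.

    lambda_LR = -2 (L_noboost - L_withboost), clamped at 0; under the
    no-boost model it is asymptotically chi-square with 1 df, from which
    the upper-tail p-value is taken.
    """
    if fit_no_boost.model_variant != "no_boost" or \
            fit_with_boost.model_variant != "with_boost":
        raise ValueError("arguments must be (no_boost fit, with_boost fit)")
    c0, c1 = fit_no_boost.counts, fit_with_boost.counts
    if c0 is None or c1 is None or not (
        np.array_equal(c0.n, c1.n) and np.array_equal(c0.mu, c1.mu)
    ):
        raise ValueError("fits were obtained on different data")
    lam = max(0.0, -2.0 * (fit_no_boost.logL - fit_with_boost.logL))
    return lam, float(chi2.sf(lam, df=1))
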