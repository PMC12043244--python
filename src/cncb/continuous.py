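"""Continuous confidence ratings with log-odds probability distortion.

Observers reporting confidence on a continuous scale are modelled as
reporting a (possibly distorted) subjective probability that their
decision was correct.  The chain per trial is

    x = D * w  ->  p = g(x)  ->  r = pi(p),

where g maps signed confidence evidence to the model-implied probability
of being correct under the design prior, and pi is the linear-in-log-odds
distortion

    Lo(pi(p)) = gamma Lo(p) + (1 - gamma) Lo(p0),   Lo(p) = log(p/(1-p)),

with fixed point p0 and slope gamma (gamma = 1 is the identity for any
p0).  The rating density follows by change of variables, so the model is
fitted to raw continuous ratings without binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

from .exceptions import ModelMisconfigurationError
from .model import ConfidenceParams, SensoryParams
from .simulate import simulate_trials

__all__ = [
    "DistortionParams",
    "ContinuousFitResult",
    "log_odds",
    "distort",
    "undistort",
    "evidence_to_probability",
    "rating_density",
    "simulate_continuous_dataset",
    "fit_continuous",
]

RATING_CLIP = 1e-4  # ratings are clipped to [RATING_CLIP, 1 - RATING_CLIP]
_GAMMA_IDENT_TOL = 0.05  # |gamma - 1| below this flags p0 as unidentified


@dataclass(frozen=True)
class DistortionParams:
    """Linear-in-log-odds probability distortion (slope gamma, fixed
    point p0)."""

    gamma: float = 1.0
    p0: float = 0.5

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")


def log_odds(p):
    """Lo(p) = log(p / (1 - p)); domain (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("log-odds requires p in (0, 1)")
    out = logit(p)
    return float(out) if out.ndim == 0 else out


def distort(p, dist: DistortionParams):
    """Subjective probability pi(p) under the log-odds distortion."""
    lo = log_odds(p)
    lo0 = float(logit(dist.p0))
    out = expit(dist.gamma * lo + (1.0 - dist.gamma) * lo0)
    return float(out) if np.ndim(out) == 0 else out


def undistort(r, dist: DistortionParams):
    """Inverse of :func:`distort`: the objective probability reported as r."""
    lo = log_odds(r)
    lo0 = float(logit(dist.p0))
    out = expit((lo - (1.0 - dist.gamma) * lo0) / dist.gamma)
    return float(out) if np.ndim(out) == 0 else out


def _distort_deriv(p, dist: DistortionParams):
    """d pi / d p in closed form (positive for gamma > 0)."""
    p = np.asarray(p, dtype=float)
    pi_p = distort(p, dist)
    return pi_p * (1.0 - pi_p) * dist.gamma / (p * (1.0 - p))


def _decision_evidence_density(sens: SensoryParams, conf: ConfidenceParams,
                               v: np.ndarray) -> np.ndarray:
    """Joint density/probability f[i, j](v) of decision j and confidence
    evidence w = v, per stimulus; shape (n_stim, 2, len(v))."""
    v = np.atleast_1d(np.asarray(v, dtype=float))
    one_ma = 1.0 - conf.alpha
    var_w = one_ma**2 + conf.sigma_c**2
    if var_w <= 0:
        raise ModelMisconfigurationError(
            "confidence evidence is deterministic (sigma_c = 0, alpha = 1)"
        )
    sd_w = np.sqrt(var_w)
    mean_w = (sens.mu - sens.theta_s) / sens.sigma_s
    # s | w is normal with sd sigma_s * sigma_c / sd_w
    slope = one_ma * sens.sigma_s / var_w
    sd_cond = sens.sigma_s * conf.sigma_c / sd_w
    out = np.empty((sens.n_stimuli, 2, v.size))
    for i in range(sens.n_stimuli):
        z = (v - mean_w[i]) / sd_w
        dens_w = np.exp(-0.5 * z * z) / (sd_w * np.sqrt(2 * np.pi))
        m_cond = sens.mu[i] + slope * (v - mean_w[i])
        if sd_cond > 0:
            p_above = ndtr((m_cond - sens.theta_s) / sd_cond)
        else:
            p_above = np.where(m_cond > sens.theta_s, 1.0,
                               np.where(m_cond < sens.theta_s, 0.0, 0.5))
        out[i, 1, :] = dens_w * p_above
        out[i, 0, :] = dens_w * (1.0 - p_above)
    return out


def evidence_to_probability(
    x,
    sens: SensoryParams,
    conf: ConfidenceParams,
    prior: np.ndarray | None = None,
    mode: str = "correct",
):
    """Model-implied probability that the decision is correct given the
    signed confidence evidence x = D * w.

    The probability is computed by Bayes' rule from the mixture of
    per-stimulus evidence distributions under ``prior`` (uniform over the
    design strengths by default), conditioning on the signed evidence
    only.  ``mode='self_consistent'`` scores decisions against
    sign(mu - theta_s) instead of sign(mu).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    scalar = x.size == 1 and np.ndim(x) <= 1
    pri = np.full(sens.n_stimuli, 1.0 / sens.n_stimuli) if prior is None \
        else np.asarray(prior, float) / np.sum(prior)
    ref = sens.mu if mode == "correct" else sens.mu - sens.theta_s
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    for j, sign in ((0, -1.0), (1, 1.0)):
        f = _decision_evidence_density(sens, conf, sign * x)  # w = j*x
        for i in range(sens.n_stimuli):
            den += pri[i] * f[i, j, :]
            if (ref[i] > 0) == (sign > 0) or (ref[i] == 0 and sign > 0):
                num += pri[i] * f[i, j, :]
    p = num / np.maximum(den, 1e-300)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(p[0]) if scalar and p.size == 1 else p


_GRID_TAIL = 1e-6  # signed-evidence mass excluded at each end of the grid


def _evidence_grid(sens: SensoryParams, conf: ConfidenceParams,
                   n: int = 801) -> np.ndarray:
    """Grid over signed evidence covering all but ~1e-6 of its mass.

    The extreme tails are excluded: they carry negligible probability but
    ratios of underflowing densities there are numerically meaningless.
    """
    from .model import signed_evidence_cdf

    one_ma = 1.0 - conf.alpha
    sd_w = np.sqrt(one_ma**2 + conf.sigma_c**2)
    span = float(np.max(np.abs((sens.mu - sens.theta_s) / sens.sigma_s)))
    lim = span + 9.0 * max(sd_w, 0.1)
    probe = np.linspace(-lim, lim, 128)
    cdf = signed_evidence_cdf(sens, conf, probe).mean(axis=0)
    lo = float(np.interp(_GRID_TAIL, cdf, probe))
    hi = float(np.interp(1.0 - _GRID_TAIL, cdf, probe))
    return np.linspace(lo, hi, n)


def _g_on_grid(sens, conf, prior, mode, n: int = 801):
    """g evaluated on a cached evidence grid; raises when not monotone."""
    xg = _evidence_grid(sens, conf, n)
    pg = evidence_to_probability(xg, sens, conf, prior, mode)
    if np.any(np.diff(pg) <= 0):
        raise ModelMisconfigurationError(
            "evidence-to-probability map is not monotone on the grid"
        )
    return xg, pg


def rating_density(
    r,
    i: int,
    j: int,
    sens: SensoryParams,
    conf: ConfidenceParams,
    dist: DistortionParams,
    prior: np.ndarray | None = None,
    mode: str = "correct",
):
    """Joint density of decision j (+/-1) and continuous rating r given
    stimulus i, via change of variables through r = pi(g(x)).

    Summed over j and integrated over the rating range, the density is 1
    for each stimulus.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any((r < RATING_CLIP) | (r > 1 - RATING_CLIP)):
        raise ValueError(f"ratings must lie in [{RATING_CLIP}, {1 - RATING_CLIP}]")
    xg, pg = _g_on_grid(sens, conf, prior, mode)
    p = undistort(r, dist)
    x = np.interp(p, pg, xg)
    gprime = np.interp(x, xg, np.gradient(pg, xg))
    drdx = _distort_deriv(np.clip(p, 1e-12, 1 - 1e-12), dist) * gprime
    sign = 1.0 if j > 0 else -1.0
    jj = 1 if j > 0 else 0
    f = _decision_evidence_density(sens, conf, sign * x)[i, jj, :]
    out = f / np.maximum(np.abs(drdx), 1e-300)
    return float(out[0]) if out.size == 1 and np.ndim(r) <= 1 else out


def simulate_continuous_dataset(
    sens: SensoryParams,
    conf: ConfidenceParams,
    dist: DistortionParams,
    n_trials: int = 10_000,
    rng: np.random.Generator | None = None,
    prior: np.ndarray | None = None,
    mode: str = "correct",
) -> pd.DataFrame:
    """Simulate trials whose confidence is reported as a distorted
    subjective probability on (0, 1)."""
    if rng is None:
        rng = np.random.default_rng()
    trials = simulate_trials(
        sens, ConfidenceParams(conf.sigma_c, conf.alpha, None), n_trials, rng
    )
    xg, pg = _g_on_grid(sens, conf, prior, mode)
    p = np.interp(trials["evidence"].to_numpy(), xg, pg)
    r = np.clip(distort(np.clip(p, 1e-12, 1 - 1e-12), dist),
                RATING_CLIP, 1 - RATING_CLIP)
    out = trials[["stimulus_index", "stimulus", "response"]].copy()
    out["confidence_cont"] = r
    return out


@dataclass(frozen=True)
class ContinuousFitResult:
    """ML fit of the continuous-rating model."""

    sens: SensoryParams
    conf: ConfidenceParams
    dist: DistortionParams
    logL: float
    converged: bool
    p0_identified: bool
    starts: tuple = ()


def fit_continuous(
    trials: pd.DataFrame,
    prior: np.ndarray | None = None,
    mode: str = "correct",
    options: dict | None = None,
) -> ContinuousFitResult:
    """Binning-free maximum-likelihood fit to continuous confidence ratings.

    Estimates (sigma_s, theta_s, sigma_c, alpha, gamma, p0) from a trial
    table with columns ``stimulus``, ``response``, ``confidence_cont``.
    When the estimated gamma is within 0.05 of 1 the distortion is
    effectively the identity and p0 is reported as unidentified.
    """
    opts = {"starts": None, "nm_maxiter": None, "grid_n": 301}
    opts.update(options or {})
    required = {"stimulus", "response", "confidence_cont"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    mu = np.sort(trials["stimulus"].unique())
    if mu.size < 2:
        raise ValueError("fitting needs >= 2 stimuli")
    r = np.clip(trials["confidence_cont"].to_numpy(float),
                RATING_CLIP, 1 - RATING_CLIP)
    resp = trials["response"].to_numpy()
    i_idx = np.searchsorted(mu, trials["stimulus"].to_numpy())
    j_idx = (resp > 0).astype(int)
    sign = np.where(j_idx == 1, 1.0, -1.0)

    def nll(x):
        try:
            sens = SensoryParams(mu=mu, sigma_s=float(np.exp(np.clip(x[0], -8, 8))),
                                 theta_s=float(np.clip(x[1], -20, 20)))
            conf = ConfidenceParams(
                sigma_c=float(np.exp(np.clip(x[2], np.log(1e-4), 8))),
                alpha=float(expit(np.clip(x[3], -13, 13))),
                boundaries=None,
            )
            dist = DistortionParams(gamma=float(np.exp(np.clip(x[4], -4, 4))),
                                    p0=float(expit(np.clip(x[5], -8, 8))))
            xg, pg = _g_on_grid(sens, conf, prior, mode, n=opts["grid_n"])
        except ModelMisconfigurationError:
            return 1e12
        p = undistort(r, dist)
        xv = np.interp(p, pg, xg)
        gprime = np.interp(xv, xg, np.gradient(pg, xg))
        drdx = _distort_deriv(np.clip(p, 1e-12, 1 - 1e-12), dist) * gprime
        f = _decision_evidence_density(sens, conf, sign * xv)
        fv = f[i_idx, j_idx, np.arange(xv.size)]
        dens = fv / np.maximum(np.abs(drdx), 1e-300)
        # ratings clipped at the scale ends lump the tail mass; keep a floor
        return -float(np.sum(np.log(np.maximum(dens, 1e-12))))

    # Type 1 start from probit margins
    from .fit import _type1_start
    from .data import trials_to_counts

    t1 = trials[["stimulus", "response"]].copy()
    t1["confidence"] = 1
    sig0, th0 = _type1_start(trials_to_counts(t1, m=1, mu=mu))

    if opts["starts"] is not None:
        start_list = list(opts["starts"])
    else:
        start_list = [(sc, a, g) for sc in (0.5, 2.0) for a in (0.25, 0.75)
                      for g in (0.5, 2.0)]
    best = None
    diagnostics = []
    for sc0, a0, g0 in start_list:
        x0 = np.array([np.log(sig0), th0, np.log(sc0), logit(a0), np.log(g0),
                       0.0])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": opts["nm_maxiter"] or 70 * x0.size,
                                "fatol": 1e-6, "xatol": 1e-5, "adaptive": True})
        diagnostics.append({"sigma_c0": sc0, "alpha0": a0, "gamma0": g0,
                            "logL": -float(res.fun),
                            "converged": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    # quasi-Newton refinement of the best simplex solution
    res2 = minimize(nll, best.x, method="L-BFGS-B",
                    options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 100})
    if res2.fun <= best.fun:
        best = res2
    diagnostics.append({"stage": "polish", "logL": -float(best.fun),
                        "converged": bool(best.success)})

    x = best.x
    sens = SensoryParams(mu=mu, sigma_s=float(np.exp(x[0])), theta_s=float(x[1]))
    conf = ConfidenceParams(sigma_c=float(np.exp(x[2])),
                            alpha=float(expit(np.clip(x[3], -13, 13))),
                            boundaries=None)
    dist = DistortionParams(gamma=float(np.exp(x[4])),
                            p0=float(expit(np.clip(x[5], -8, 8))))
    return ContinuousFitResult(
        sens=sens,
        conf=conf,
        dist=dist,
        logL=-float(best.fun),
        converged=any(d["converged"] for d in diagnostics),
        p0_identified=bool(abs(dist.gamma - 1.0) > _GAMMA_IDENT_TOL),
        starts=tuple(diagnostics),
    )
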