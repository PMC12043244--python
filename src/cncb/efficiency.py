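"""Confidence efficiency via equivalent confidence noise.

A given pattern of Type 2 behaviour can be produced by a continuum of
(confidence noise, confidence boost) pairs; the continuum is summarized
by its extreme member with boost 1, whose confidence noise tau is the
*equivalent confidence noise*.  At boost 1 the confidence evidence
w = (mu - theta_s)/sigma_s + eps_c is independent of the sensory sample,
so the model factorizes into the Type 1 term times a one-dimensional
interval probability, and tau is well defined by projection.

Efficiency compares the human observer with the ideal confidence
observer (no confidence noise, no boost, boundaries matched to the human
marginal rating distribution):

    eta = tau_ideal^2 / tau_human^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, root

from .exceptions import EfficiencyRangeError
from .model import (
    ConfidenceParams,
    ProbTable,
    SensoryParams,
    Type2Point,
    _correct_index,
    response_probabilities,
    type2_rates,
)
from .simulate import calibrate_boundaries

__all__ = [
    "EfficiencyResult",
    "equivalent_noise",
    "ideal_observer",
    "cncb_efficiency",
    "self_consistency_rates",
]

_TAU_BRACKET = (1e-3, 1e3)


@dataclass(frozen=True)
class EfficiencyResult:
    """Equivalent noises and their ratio of squares."""

    tau_human: float
    tau_ideal: float
    eta: float
    ideal_boundaries: np.ndarray
    mode: str

    def __post_init__(self):
        if abs(self.eta - self.tau_ideal**2 / self.tau_human**2) > 1e-9:
            raise ValueError("eta inconsistent with the equivalent noises")


def _pooled_point(table: ProbTable, sens: SensoryParams, mode: str,
                  t: int = 0) -> Type2Point:
    """Pooled Type 2 hit/FA of an arbitrary probability table."""
    jc = _correct_index(sens, mode)
    w = np.full(table.p.shape[0], 1.0 / table.p.shape[0])
    idx = np.arange(table.p.shape[0])
    p_corr = table.p[idx, jc, :]
    p_err = table.p[idx, 1 - jc, :]
    hit = np.dot(w, p_corr[:, t + 1:].sum(axis=1)) / np.dot(w, p_corr.sum(axis=1))
    fa = np.dot(w, p_err[:, t + 1:].sum(axis=1)) / np.dot(w, p_err.sum(axis=1))
    return Type2Point(fa2=float(fa), hit2=float(hit), boundary_index=t,
                      stimulus_group="pooled")


def _alpha1_table(sens: SensoryParams, tau: float, boundaries) -> ProbTable:
    conf = ConfidenceParams(sigma_c=tau, alpha=1.0,
                            boundaries=np.asarray(boundaries, float))
    return response_probabilities(sens, conf)


def _equivalent_noise_kl(sens: SensoryParams, target: ProbTable):
    """KL projection of the target table onto the boost-1 family.

    Minimizes the cross-entropy -sum_i w_i sum_{j,k} p_t log p_model over
    (log tau, ordered boundaries); with the sensory parameters fixed this
    is equivalent to minimizing the KL divergence per stimulus with equal
    weights.
    """
    pt = target.p
    m = pt.shape[2]

    def unpack(x):
        tau = float(np.exp(np.clip(x[0], np.log(_TAU_BRACKET[0]) - 2,
                                   np.log(_TAU_BRACKET[1]) + 2)))
        b = np.concatenate([[x[1]], x[1] + np.cumsum(np.exp(np.clip(x[2:], -20, 20)))])
        return tau, b

    def objective(x):
        tau, b = unpack(x)
        try:
            pm = _alpha1_table(sens, tau, b).p
        except Exception:
            return 1e12
        return -float(np.sum(pt * np.log(np.maximum(pm, 1e-12)))) / pt.shape[0]

    # initialize boundaries so the boost-1 model at tau = 1 matches the
    # target's pooled rating marginals
    q = np.maximum(target.level_marginals(), 1e-9)
    q /= q.sum()
    b0 = calibrate_boundaries(sens, 1.0, 1.0, q)
    x0 = np.concatenate([[0.0], [b0[0]], np.log(np.maximum(np.diff(b0), 1e-8))])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": 400 * x0.size, "fatol": 1e-12,
                            "xatol": 1e-9, "adaptive": True})
    res2 = minimize(objective, res.x, method="L-BFGS-B",
                    options={"ftol": 1e-15, "gtol": 1e-10})
    if res2.fun <= res.fun:
        res = res2
    tau, b = unpack(res.x)
    if not _TAU_BRACKET[0] * 1.5 < tau < _TAU_BRACKET[1] / 1.5:
        raise EfficiencyRangeError(
            "equivalent noise ran into its search bracket; the target Type 2 "
            "behaviour is outside the boost-1 attainable range"
        )
    return tau, b


def _equivalent_noise_rates(sens: SensoryParams, target: ProbTable, mode: str):
    """Two-level reduction: solve the Type 2 hit/FA equations for
    (tau, b) by root-finding."""
    point = _pooled_point(target, sens, mode, t=0)
    if point.hit2 <= point.fa2 + 1e-12:
        raise EfficiencyRangeError("target Type 2 performance is at or below chance")

    def eqs(x):
        tau = float(np.exp(x[0]))
        tbl = _alpha1_table(sens, tau, [x[1]])
        p = _pooled_point(tbl, sens, mode, t=0)
        return [p.hit2 - point.hit2, p.fa2 - point.fa2]

    sol = root(eqs, x0=[0.0, float(np.median(target.boundaries))],
               method="hybr", tol=1e-12)
    tau = float(np.exp(sol.x[0]))
    resid = np.max(np.abs(eqs(sol.x)))
    if not sol.success or resid > 1e-8 or not \
            _TAU_BRACKET[0] < tau < _TAU_BRACKET[1]:
        raise EfficiencyRangeError(
            "no boost-1 observer reproduces the target Type 2 point "
            f"(residual {resid:.2e})"
        )
    return tau, np.array([sol.x[1]])


def equivalent_noise(
    sens: SensoryParams,
    target: ProbTable,
    mode: str = "correct",
    method: str = "auto",
) -> tuple[float, np.ndarray]:
    """Equivalent confidence noise of a target probability table.

    ``method='kl'`` projects the full table onto the boost-1 family by KL
    divergence (general case); ``'rates'`` solves the two-level Type 2
    hit/false-alarm equations (only valid for two rating levels);
    ``'auto'`` picks 'rates' for two symmetric-design levels and 'kl'
    otherwise.  Both paths agree to high accuracy in the two-level case.
    """
    if method == "auto":
        method = "rates" if (target.p.shape[2] == 2 and sens.theta_s == 0.0) else "kl"
    if method == "rates":
        if target.p.shape[2] != 2:
            raise ValueError("'rates' method applies to two-level tables only")
        return _equivalent_noise_rates(sens, target, mode)
    if method == "kl":
        return _equivalent_noise_kl(sens, target)
    raise ValueError("method must be 'auto', 'kl' or 'rates'")


def ideal_observer(sens: SensoryParams, marginal_proportions) -> ConfidenceParams:
    """The ideal confidence observer for a design: no confidence noise, no
    boost, boundaries calibrated so its pooled rating marginals equal the
    human ones."""
    b = calibrate_boundaries(sens, 0.0, 0.0, marginal_proportions)
    return ConfidenceParams(sigma_c=0.0, alpha=0.0, boundaries=b)


def cncb_efficiency(fit, mode: str = "correct",
                    method: str = "auto") -> EfficiencyResult:
    """Confidence efficiency eta = tau_ideal^2 / tau_human^2 of a fitted
    (or constructed) observer.

    ``fit`` is either a :class:`~cncb.fit.FitResult` or a ``(sens, conf)``
    pair.  The ideal observer's boundaries are matched to the observer's
    own pooled rating marginals before its equivalent noise is computed.
    """
    if hasattr(fit, "sens"):
        if not getattr(fit, "converged", True):
            warnings.warn("efficiency computed from a non-converged fit",
                          stacklevel=2)
        sens, conf = fit.sens, fit.conf
    else:
        sens, conf = fit
    if conf.boundaries is None:
        # continuous-rating fit: summarize on an equal-proportion 4-level scale
        b = calibrate_boundaries(sens, conf.sigma_c, conf.alpha, np.full(4, 0.25))
        conf = ConfidenceParams(conf.sigma_c, conf.alpha, b)
    table_h = response_probabilities(sens, conf)
    tau_h, _ = equivalent_noise(sens, table_h, mode=mode, method=method)
    ideal = ideal_observer(sens, table_h.level_marginals())
    table_i = response_probabilities(sens, ideal)
    tau_i, _ = equivalent_noise(sens, table_i, mode=mode, method=method)
    return EfficiencyResult(
        tau_human=tau_h,
        tau_ideal=tau_i,
        eta=tau_i**2 / tau_h**2,
        ideal_boundaries=ideal.boundaries,
        mode=mode,
    )


def self_consistency_rates(
    sens: SensoryParams,
    conf: ConfidenceParams,
    boundary_index: int = 0,
) -> list[Type2Point]:
    """Type 2 rates conditioned on self-consistency: the decision matching
    sign(mu - theta_s) rather than objective correctness."""
    return type2_rates(sens, conf, boundary_index, mode="self_consistent")
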