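"""Generative model of perceptual decisions and confidence ratings.

The model describes one trial in two steps.  Sensory evidence is the
stimulus strength corrupted by Gaussian sensory noise,

    s = mu_s + eps_s,        eps_s ~ N(0, sigma_s^2),

and the perceptual (Type 1) decision compares it to a sensory criterion,
D = sign(s - theta_s).  Confidence (Type 2) is based on confidence
evidence

    w = (mu_s + (1 - alpha) eps_s - theta_s) / sigma_s + eps_c,
    eps_c ~ N(0, sigma_c^2),

where ``alpha`` (confidence boost) is the weight given to direct stimulus
information over the sensory sample, and ``sigma_c`` (confidence noise)
degrades the confidence judgment beyond the sensory limit.  A rating on an
m-point scale discretizes the signed confidence evidence D*w with m - 1
ordered boundaries: the lowest category spans D*w in (-inf, b_1], so it
includes confidence evidence that contradicts the decision itself.

Because (s, w) are jointly Gaussian, all response probabilities are
bivariate-normal rectangle probabilities; they are computed exactly here
(see :mod:`cncb._bvn`), with degenerate cases (sigma_c = 0, or correlation
numerically at 1) routed to exact one-dimensional reductions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from ._bvn import bvn_cdf
from .exceptions import (
    DegenerateStimulusWarning,
    NumericalError,
    UndefinedRateError,
)

__all__ = [
    "SensoryParams",
    "ConfidenceParams",
    "BivariateMoments",
    "ProbTable",
    "Type2Point",
    "joint_moments",
    "response_probabilities",
    "prob_correct",
    "type2_rates",
    "pooled_type2_rates",
    "type2_auc",
]

# correlations above this are routed to the exact singular reduction
_RHO_SINGULAR = 1.0 - 1e-9


@dataclass(frozen=True)
class SensoryParams:
    """Type 1 parameters: stimulus strengths, sensory noise and criterion.

    Parameters
    ----------
    mu : array_like
        Stimulus strengths, at least two distinct values, sorted ascending.
    sigma_s : float
        Sensory noise standard deviation (> 0).
    theta_s : float
        Sensory criterion.
    """

    mu: np.ndarray
    sigma_s: float = 1.0
    theta_s: float = 0.0

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "mu", mu)
        if mu.size < 2 or np.unique(mu).size < 2:
            raise ValueError("mu must contain at least two distinct strengths")
        if np.any(np.diff(mu) < 0):
            raise ValueError("mu must be sorted ascending")
        if not self.sigma_s > 0:
            raise ValueError("sigma_s must be > 0")

    @property
    def n_stimuli(self) -> int:
        return self.mu.size


@dataclass(frozen=True)
class ConfidenceParams:
    """Type 2 parameters: confidence noise, boost, and rating boundaries.

    ``boundaries`` may be ``None`` for the continuous-rating regime where
    no discretization is applied.
    """

    sigma_c: float
    alpha: float
    boundaries: np.ndarray | None = None

    def __post_init__(self):
        if not self.sigma_c >= 0:
            raise ValueError("sigma_c must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.boundaries is not None:
            b = np.atleast_1d(np.asarray(self.boundaries, dtype=float))
            object.__setattr__(self, "boundaries", b)
            if b.size >= 2 and np.any(np.diff(b) <= 0):
                raise ValueError("boundaries must be strictly increasing")

    @property
    def n_levels(self) -> int:
        if self.boundaries is None:
            raise ValueError("continuous-rating parameters have no levels")
        return self.boundaries.size + 1


@dataclass(frozen=True)
class BivariateMoments:
    """First and second moments of the joint (s, w) distribution."""

    mean_s: float
    mean_w: float
    var_s: float
    var_w: float
    cov_sw: float

    def __post_init__(self):
        if self.cov_sw**2 > self.var_s * self.var_w * (1 + 1e-12):
            raise ValueError("covariance violates Cauchy-Schwarz")

    @property
    def rho(self) -> float:
        denom = np.sqrt(self.var_s * self.var_w)
        return self.cov_sw / denom if denom > 0 else 1.0


@dataclass(frozen=True)
class ProbTable:
    """Model probabilities p[i, j, k] of decision j and rating k given
    stimulus i; j index 0 codes decision -1, index 1 codes +1."""

    p: np.ndarray
    mu: np.ndarray
    boundaries: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if not np.all(np.isfinite(p)):
            raise NumericalError("non-finite response probabilities")
        if np.any(p < 0):
            raise NumericalError("negative response probabilities")
        sums = p.sum(axis=(1, 2))
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise NumericalError("response probabilities do not sum to 1")

    @property
    def n_levels(self) -> int:
        return self.p.shape[2]

    def level_marginals(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Pooled P(rating = k), with equal stimulus weights by default."""
        w = np.full(self.p.shape[0], 1.0 / self.p.shape[0]) if weights is None \
            else np.asarray(weights, float) / np.sum(weights)
        return np.einsum("i,ijk->k", w, self.p)


@dataclass(frozen=True)
class Type2Point:
    """One point of a Type 2 ROC: false-alarm and hit rate at a boundary."""

    fa2: float
    hit2: float
    boundary_index: int
    stimulus_group: object = None


def joint_moments(sens: SensoryParams, conf: ConfidenceParams, i: int) -> BivariateMoments:
    """Moments of the bivariate normal (s, w) for stimulus index ``i``.

    Direct algebraic consequence of the two evidence equations:
    E[w] = (mu_i - theta_s)/sigma_s, Var[w] = (1-alpha)^2 + sigma_c^2 and
    Cov[s, w] = (1-alpha) sigma_s.
    """
    mu_i = float(sens.mu[i])
    one_ma = 1.0 - conf.alpha
    return BivariateMoments(
        mean_s=mu_i,
        mean_w=(mu_i - sens.theta_s) / sens.sigma_s,
        var_s=sens.sigma_s**2,
        var_w=one_ma**2 + conf.sigma_c**2,
        cov_sw=one_ma * sens.sigma_s,
    )


def _w_geometry(sens: SensoryParams, conf: ConfidenceParams):
    """Shared per-stimulus quantities for rectangle probabilities."""
    mean_w = (sens.mu - sens.theta_s) / sens.sigma_s
    one_ma = 1.0 - conf.alpha
    var_w = one_ma**2 + conf.sigma_c**2
    sd_w = np.sqrt(var_w)
    # 1 - rho^2 = sigma_c^2 / var_w, cancellation-free
    rho = one_ma / sd_w if sd_w > 0 else 1.0
    omr2 = conf.sigma_c**2 / var_w if var_w > 0 else 0.0
    z_theta = (sens.theta_s - sens.mu) / sens.sigma_s  # P(s<=theta) threshold
    return mean_w, sd_w, rho, omr2, z_theta


def _edge_cdfs(sens: SensoryParams, conf: ConfidenceParams, edges):
    """Joint and marginal CDFs at a shared grid of w-values.

    Returns (J, F) with J[i, e] = P(s <= theta_s, w <= edge_e) and
    F[i, e] = P(w <= edge_e) for stimulus i, evaluated in one vectorized
    pass; degenerate geometries are routed to exact 1-D reductions.
    """
    edges = np.atleast_1d(np.asarray(edges, dtype=float))
    mean_w, sd_w, rho, omr2, z_theta = _w_geometry(sens, conf)
    one_ma = 1.0 - conf.alpha
    zt = z_theta[:, None]
    if sd_w == 0.0:
        # w is the constant mean_w (sigma_c = 0, alpha = 1)
        F = (edges[None, :] >= mean_w[:, None]).astype(float)
        return ndtr(zt) * F, F
    if rho > _RHO_SINGULAR:
        # w is (numerically) an increasing affine map of s:
        # w = mean_w + (1 - alpha) z with z = (s - mu)/sigma_s
        z_e = (edges[None, :] - mean_w[:, None]) / one_ma
        F = ndtr(z_e)
        return ndtr(np.minimum(z_e, zt)), F
    k = (edges[None, :] - mean_w[:, None]) / sd_w
    F = ndtr(k)
    finite = np.isfinite(edges)
    if finite.all():
        J = bvn_cdf(np.broadcast_to(zt, k.shape), k, rho, omr2)
    else:
        J = np.empty_like(k)
        kf = k[:, finite]
        J[:, finite] = bvn_cdf(np.broadcast_to(zt, kf.shape), kf, rho, omr2)
        J[:, np.isneginf(edges)] = 0.0
        J[:, np.isposinf(edges)] = ndtr(zt)
    return J, F


def _interval_masses(sens: SensoryParams, conf: ConfidenceParams, w_lo, w_hi):
    """P(s > theta_s, w in (w_lo, w_hi]) and P(s <= theta_s, w in (w_lo, w_hi])
    per stimulus.

    ``w_lo``/``w_hi`` broadcast to shape (K,) shared by stimuli; the result
    has shape (n_stimuli, K).
    """
    w_lo = np.atleast_1d(np.asarray(w_lo, dtype=float))
    w_hi = np.atleast_1d(np.asarray(w_hi, dtype=float))
    w_lo, w_hi = np.broadcast_arrays(w_lo, w_hi)
    k = w_lo.size
    J, F = _edge_cdfs(sens, conf, np.concatenate([w_lo, w_hi]))
    below = np.clip(J[:, k:] - J[:, :k], 0.0, None)
    above = np.clip((F[:, k:] - J[:, k:]) - (F[:, :k] - J[:, :k]), 0.0, None)
    return above, below


def response_probabilities(sens: SensoryParams, conf: ConfidenceParams) -> ProbTable:
    """Exact model probabilities P(decision j, rating k | stimulus i).

    With rating edges b_0 = -inf < b_1 < ... < b_m = +inf:

    * decision +1, rating k:  P(s > theta_s and b_{k-1} < w <= b_k)
    * decision -1, rating k:  P(s <= theta_s and -b_k <= w < -b_{k-1})
    """
    if conf.boundaries is None:
        raise ValueError("rating boundaries are required for a discrete table")
    edges = np.concatenate([[-np.inf], conf.boundaries, [np.inf]])
    m = conf.n_levels
    # one vectorized CDF pass over the positive and negated edge grids
    J, F = _edge_cdfs(sens, conf, np.concatenate([edges, -edges[::-1]]))
    ne = edges.size
    above_c = F[:, :ne] - J[:, :ne]                 # P(s>th, w<=edge)
    above = np.clip(np.diff(above_c, axis=1), 0.0, None)
    # decision -1: w in [-b_k, -b_{k-1})  (interval endpoints measure-zero)
    below_c = J[:, ne:][:, ::-1]                    # P(s<=th, w<=-edge_k)
    below = np.clip(below_c[:, :-1] - below_c[:, 1:], 0.0, None)
    p = np.stack([below, above], axis=1)
    if not np.all(np.isfinite(p)):
        raise NumericalError("non-finite probabilities in response table")
    # renormalize away accumulated rounding at the 1e-15 scale
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=(1, 2), keepdims=True)
    assert p.shape == (sens.n_stimuli, 2, m)
    return ProbTable(p=p, mu=sens.mu.copy(), boundaries=conf.boundaries.copy())


def signed_evidence_cdf(sens: SensoryParams, conf: ConfidenceParams, v) -> np.ndarray:
    """Per-stimulus CDF of the signed confidence evidence V = D * w.

    P(V <= v) = P(s > theta, w <= v) + P(s <= theta, w >= -v); shape
    (n_stimuli, len(v)).
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    above, _ = _interval_masses(sens, conf, -np.inf, v)
    _, below = _interval_masses(sens, conf, -v, np.inf)
    return above + below


def prob_correct(sens: SensoryParams, i: int, convention: str = "correct") -> float:
    """Probability that the decision matches the stimulus category.

    ``convention='correct'`` scores against sign(mu_i) (objective accuracy);
    ``'self_consistent'`` against sign(mu_i - theta_s), the category the
    observer's own criterion assigns to the stimulus.
    """
    mu_i = float(sens.mu[i])
    target = mu_i if convention == "correct" else mu_i - sens.theta_s
    if convention == "self_consistent" and target == 0.0:
        raise UndefinedRateError("stimulus lies exactly on the criterion")
    if target == 0.0:
        warnings.warn(
            "stimulus strength equals the reference point; accuracy is 0.5",
            DegenerateStimulusWarning,
            stacklevel=2,
        )
        return 0.5
    p_plus = 1.0 - ndtr((sens.theta_s - mu_i) / sens.sigma_s)
    return p_plus if target > 0 else 1.0 - p_plus


def _correct_index(sens: SensoryParams, mode: str) -> np.ndarray:
    """Decision index (0 for -1, 1 for +1) scored as 'correct' per stimulus."""
    ref = sens.mu if mode == "correct" else sens.mu - sens.theta_s
    if np.any(ref == 0.0):
        if mode == "correct":
            warnings.warn(
                "a stimulus equals the criterion reference; its decisions are "
                "scored against sign 0 -> treated as +1",
                DegenerateStimulusWarning,
                stacklevel=3,
            )
        else:
            raise UndefinedRateError("stimulus lies exactly on the criterion")
    return (ref >= 0).astype(int)


def type2_rates(
    sens: SensoryParams,
    conf: ConfidenceParams,
    boundary_index: int = 0,
    mode: str = "correct",
) -> list[Type2Point]:
    """Per-stimulus Type 2 hit / false-alarm rates at one rating boundary.

    A 'hit' is a rating above boundary ``b_{boundary_index+1}`` on a correct
    (or self-consistent) decision; a false alarm is the same rating event on
    an incorrect (inconsistent) decision.
    """
    if mode not in ("correct", "self_consistent"):
        raise ValueError("mode must be 'correct' or 'self_consistent'")
    table = response_probabilities(sens, conf)
    t = boundary_index
    if not 0 <= t < table.n_levels - 1:
        raise ValueError("boundary_index out of range")
    jc = _correct_index(sens, mode)
    points = []
    for i in range(sens.n_stimuli):
        p_corr = table.p[i, jc[i], :]
        p_err = table.p[i, 1 - jc[i], :]
        den_h, den_f = p_corr.sum(), p_err.sum()
        if den_h <= 1e-300 or den_f <= 1e-300:
            raise UndefinedRateError(
                f"zero-probability conditioning set for stimulus {i}"
            )
        points.append(
            Type2Point(
                fa2=float(p_err[t + 1:].sum() / den_f),
                hit2=float(p_corr[t + 1:].sum() / den_h),
                boundary_index=t,
                stimulus_group=i,
            )
        )
    return points


def pooled_type2_rates(
    sens: SensoryParams,
    conf: ConfidenceParams,
    boundary_index: int = 0,
    mode: str = "correct",
    weights: np.ndarray | None = None,
) -> Type2Point:
    """Type 2 rates pooled over stimuli with equal (or given) weights."""
    table = response_probabilities(sens, conf)
    t = boundary_index
    jc = _correct_index(sens, mode)
    w = np.full(sens.n_stimuli, 1.0 / sens.n_stimuli) if weights is None \
        else np.asarray(weights, float) / np.sum(weights)
    hit_n = fa_n = hit_d = fa_d = 0.0
    for i in range(sens.n_stimuli):
        p_corr = table.p[i, jc[i], :]
        p_err = table.p[i, 1 - jc[i], :]
        hit_n += w[i] * p_corr[t + 1:].sum()
        hit_d += w[i] * p_corr.sum()
        fa_n += w[i] * p_err[t + 1:].sum()
        fa_d += w[i] * p_err.sum()
    if hit_d <= 1e-300 or fa_d <= 1e-300:
        raise UndefinedRateError("zero-probability conditioning set")
    return Type2Point(fa2=float(fa_n / fa_d), hit2=float(hit_n / hit_d),
                      boundary_index=t, stimulus_group="pooled")


def type2_auc(
    sens: SensoryParams,
    conf: ConfidenceParams,
    mode: str = "correct",
    n_grid: int = 2001,
) -> float:
    """Area under the pooled Type 2 ROC traced by sweeping the boundary.

    The boundary runs over the whole real line; the curve goes from (1, 1)
    (everything rated high) to (0, 0) and the area is computed by
    trapezoidal quadrature on a wide evidence grid.
    """
    mean_w, sd_w, _, _, _ = _w_geometry(sens, conf)
    span = np.max(np.abs(mean_w)) + 8.5 * max(sd_w, 1e-3)
    grid = np.linspace(-span, span, n_grid)
    above, _ = _interval_masses(sens, conf, grid, np.inf)     # P(s>th, w>b)
    _, below = _interval_masses(sens, conf, -np.inf, -grid)   # P(s<=th, -w>b)
    jc = _correct_index(sens, mode)
    w = np.full(sens.n_stimuli, 1.0 / sens.n_stimuli)
    idx = np.arange(sens.n_stimuli)
    high = np.stack([below, above], axis=1)   # P(D=j, D.w > b | i), (n, 2, b)
    p_plus = 1.0 - ndtr((sens.theta_s - sens.mu) / sens.sigma_s)
    p_dec = np.stack([1.0 - p_plus, p_plus], axis=1)  # P(D=j | i), (n, 2)
    hit_n = np.einsum("i,ib->b", w, high[idx, jc])
    hit_d = float(np.dot(w, p_dec[idx, jc]))
    fa_n = np.einsum("i,ib->b", w, high[idx, 1 - jc])
    fa_d = float(np.dot(w, p_dec[idx, 1 - jc]))
    hit = np.concatenate([[1.0], hit_n / hit_d, [0.0]])
    fa = np.concatenate([[1.0], fa_n / fa_d, [0.0]])
    order = np.argsort(fa)
    return float(np.trapezoid(hit[order], fa[order]))
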