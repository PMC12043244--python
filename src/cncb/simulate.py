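"""Trial simulation, boundary calibration and study designs.

The simulator draws trials directly from the generative equations: one
sensory noise sample per trial feeds both the decision and the confidence
evidence (the same eps_s realization appears in both), a confidence noise
sample is added, and the rating discretizes the signed evidence D*w.
Boundary calibration solves for rating boundaries that give the model a
prescribed marginal distribution of confidence levels, pooled over
stimuli with equal weights -- the construction used throughout the
simulation studies, where trial counts per stimulus are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import mannwhitneyu

from .data import RatingCounts, trials_to_counts
from .exceptions import CalibrationError
from .model import ConfidenceParams, SensoryParams, signed_evidence_cdf

__all__ = [
    "SimulationDesign",
    "StudyRanges",
    "triangular_proportions",
    "calibrate_boundaries",
    "simulate_trials",
    "simulate_dataset",
    "study_parameter_ranges",
    "equally_spaced_strengths",
    "sigma_for_proportion_correct",
    "discriminability_auc",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one simulated experiment.

    ``target_proportions`` overrides the triangular rule when given;
    otherwise the marginal rating distribution is the triangular profile
    with top/bottom ratio ``delta`` (``delta = 1``: uniform levels).
    """

    n_trials: int = 10_000
    n_levels: int = 4
    delta: float = 1.0
    target_proportions: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.n_levels < 2:
            raise ValueError("at least two confidence levels are required")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.target_proportions is not None:
            p = np.asarray(self.target_proportions, dtype=float)
            if p.size != self.n_levels or np.any(p <= 0) or abs(p.sum() - 1) > 1e-12:
                raise ValueError("target_proportions must be a positive simplex "
                                 "vector of length n_levels")
            object.__setattr__(self, "target_proportions", p)

    @property
    def proportions(self) -> np.ndarray:
        if self.target_proportions is not None:
            return self.target_proportions
        return triangular_proportions(self.n_levels, self.delta)


def triangular_proportions(m: int, delta: float) -> np.ndarray:
    """Linearly increasing (or decreasing) level proportions.

    p_k is proportional to 1 + (delta - 1)(k - 1)/(m - 1), so the ratio of
    top to bottom level is exactly ``delta`` and ``delta = 1`` is uniform.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if not delta > 0:
        raise ValueError("delta must be positive")
    k = np.arange(m, dtype=float)
    p = 1.0 + (delta - 1.0) * k / (m - 1)
    return p / p.sum()


def calibrate_boundaries(
    sens: SensoryParams,
    sigma_c: float,
    alpha: float,
    target_proportions,
) -> np.ndarray:
    """Rating boundaries that give the model the requested pooled marginals.

    Solves P(D*w <= b_t) = sum_{k<=t} q_k for each cumulative target by
    monotone root-finding on the pooled CDF of the signed confidence
    evidence (equal stimulus weights).
    """
    q = np.asarray(target_proportions, dtype=float)
    if np.any(q <= 0) or abs(q.sum() - 1.0) > 1e-9:
        raise CalibrationError("target proportions must be positive and sum to 1")
    conf = ConfidenceParams(sigma_c=sigma_c, alpha=alpha, boundaries=None)

    def pooled_cdf(v: float) -> float:
        return float(signed_evidence_cdf(sens, conf, v).mean())

    span = np.max(np.abs((sens.mu - sens.theta_s))) / sens.sigma_s
    lo, hi = -span - 60.0, span + 60.0
    bounds = []
    for c in np.cumsum(q)[:-1]:
        if not pooled_cdf(lo) < c < pooled_cdf(hi):
            raise CalibrationError(
                f"cumulative proportion {c:.3g} is numerically unreachable"
            )
        bounds.append(brentq(lambda v: pooled_cdf(v) - c, lo, hi, xtol=1e-11))
    b = np.asarray(bounds)
    if np.any(np.diff(b) <= 0):
        raise CalibrationError("calibrated boundaries are not increasing")
    return b


def simulate_trials(
    sens: SensoryParams,
    conf: ConfidenceParams,
    n_trials: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw i.i.d. trials from the generative model.

    Trials are split equally across stimuli (any remainder goes to the
    lowest-index stimuli, deterministically).  Returns a trial table with
    the raw signed evidence in column ``evidence`` alongside the rating,
    so continuous-rating simulators can reuse it.
    """
    n_stim = sens.n_stimuli
    base, rem = divmod(n_trials, n_stim)
    counts = np.full(n_stim, base) + (np.arange(n_stim) < rem)
    idx = np.repeat(np.arange(n_stim), counts)
    mu = sens.mu[idx]
    eps_s = rng.standard_normal(n_trials) * sens.sigma_s
    eps_c = rng.standard_normal(n_trials) * conf.sigma_c
    s = mu + eps_s
    d = np.where(s - sens.theta_s > 0, 1, -1)  # ties (measure zero) -> +1...
    d[s == sens.theta_s] = 1
    w = (mu + (1.0 - conf.alpha) * eps_s - sens.theta_s) / sens.sigma_s + eps_c
    v = d * w
    out = pd.DataFrame(
        {
            "stimulus_index": idx,
            "stimulus": mu,
            "response": d,
            "evidence": v,
        }
    )
    if conf.boundaries is not None:
        out["confidence"] = np.searchsorted(conf.boundaries, v, side="left") + 1
    return out


def simulate_dataset(
    sens: SensoryParams,
    conf: ConfidenceParams,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, RatingCounts]:
    """Simulate one experiment; returns the trial table and its counts."""
    if conf.boundaries is None:
        raise ValueError("discrete simulation requires rating boundaries")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    trials = simulate_trials(sens, conf, design.n_trials, rng)
    counts = trials_to_counts(
        trials[["stimulus", "response", "confidence"]], m=conf.n_levels, mu=sens.mu
    )
    return trials, counts


def equally_spaced_strengths(n: int, lo: float = -2.0, hi: float = 2.0) -> np.ndarray:
    """n strengths equally spaced on (lo, hi): n + 2 grid points on the
    closed interval with the two endpoints dropped."""
    return np.linspace(lo, hi, n + 2)[1:-1]


def sigma_for_proportion_correct(pc: float, mu: np.ndarray) -> float:
    """Sensory noise giving mean accuracy ``pc`` at the optimal criterion.

    At theta_s = 0 the accuracy on strength u is Phi(|u| / sigma_s); the
    mean over the design strengths is monotone in sigma_s, so the level is
    found by bisection.
    """
    from scipy.special import ndtr

    mu = np.abs(np.asarray(mu, dtype=float))
    if not 0.5 < pc < 1.0:
        raise ValueError("pc must lie in (0.5, 1)")

    def mean_acc(log_sig: float) -> float:
        return float(ndtr(mu / np.exp(log_sig)).mean()) - pc

    return float(np.exp(brentq(mean_acc, -15.0, 15.0, xtol=1e-12)))


@dataclass(frozen=True)
class StudyRanges:
    """Parameter-sampling specification for a simulation study."""

    study_id: str
    strengths: np.ndarray
    n_levels: int
    n_trials: int
    pc_range: tuple[float, float]          # accuracy range -> sigma_s
    theta_range: tuple[float, float]
    sigma_c_range: tuple[float, float]     # log-uniform
    alpha_range: tuple[float, float]
    delta_range: tuple[float, float]       # log-uniform
    defaults: dict = field(default_factory=dict)

    def draw(self, rng: np.random.Generator, alpha: float | None = None) -> dict:
        """Draw one parameter set; ``alpha`` overrides the sampled boost
        (e.g. 0.0 for the no-boost generating model)."""
        pc = rng.uniform(*self.pc_range)
        params = {
            "sigma_s": sigma_for_proportion_correct(pc, self.strengths),
            "theta_s": rng.uniform(*self.theta_range),
            "sigma_c": float(np.exp(rng.uniform(*np.log(self.sigma_c_range)))),
            "alpha": rng.uniform(*self.alpha_range) if alpha is None else alpha,
            "delta": float(np.exp(rng.uniform(*np.log(self.delta_range)))),
        }
        return params


def study_parameter_ranges(study_id: str) -> StudyRanges:
    """Declared sampling ranges for the simulation studies.

    * ``model_recovery`` -- six strengths in [-1.43, 1.43], 4 levels.
    * ``mratio_grid`` -- two strengths +/-0.67, 4 levels.
    * ``default`` -- the fixed default observer (sigma_c 0.5, alpha 0.2).
    """
    common = dict(
        n_trials=10_000,
        pc_range=(0.55, 0.95),
        theta_range=(-1.5, 1.5),
        sigma_c_range=(0.25, 4.0),
        alpha_range=(0.0, 1.0),
        delta_range=(0.25, 4.0),
    )
    if study_id == "model_recovery":
        return StudyRanges(
            study_id=study_id,
            strengths=np.array([-1.43, -0.86, -0.29, 0.29, 0.86, 1.43]),
            n_levels=4,
            **common,
        )
    if study_id == "mratio_grid":
        return StudyRanges(
            study_id=study_id,
            strengths=np.array([-0.67, 0.67]),
            n_levels=4,
            **common,
        )
    if study_id == "default":
        return StudyRanges(
            study_id=study_id,
            strengths=np.array([-0.67, 0.67]),
            n_levels=4,
            **common,
            defaults={"sigma_s": 1.0, "theta_s": 0.0, "sigma_c": 0.5,
                      "alpha": 0.2, "delta": 1.0},
        )
    raise ValueError(f"unknown study_id {study_id!r}")


def discriminability_auc(sample_a, sample_b) -> float:
    """Nonparametric AUC separating two samples (rank / Mann-Whitney form);
    ties count one half."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = mannwhitneyu(b, a, alternative="two-sided").statistic
    return float(u / (a.size * b.size))
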