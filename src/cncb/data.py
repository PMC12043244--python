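"""Trial-level and aggregated data containers.

Trial tables are plain :class:`pandas.DataFrame` objects with columns
``stimulus`` (strength, real), ``response`` (-1/+1) and either
``confidence`` (integer level, 1..m) or ``confidence_cont`` (real in
(0, 1)).  :class:`RatingCounts` is the aggregated n[i, j, k] tensor the
fitting routines consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RatingCounts", "trials_to_counts"]


@dataclass(frozen=True)
class RatingCounts:
    """Counts n[i, j, k] of decision j (index 0 -> -1, 1 -> +1) and rating
    k for stimulus i, with the stimulus strengths as metadata."""

    n: np.ndarray
    mu: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.n)
        if n.ndim != 3 or n.shape[1] != 2:
            raise ValueError("counts must have shape (n_stimuli, 2, m)")
        if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if mu.size != n.shape[0]:
            raise ValueError("mu length must match the first counts axis")
        if np.any(self.totals == 0):
            raise ValueError("every stimulus must have at least one trial")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "mu", mu)

    @property
    def m(self) -> int:
        """Number of confidence levels."""
        return self.n.shape[2]

    @property
    def n_stimuli(self) -> int:
        return self.n.shape[0]

    @property
    def totals(self) -> np.ndarray:
        """Per-stimulus trial totals N_i."""
        return np.asarray(self.n).sum(axis=(1, 2))

    @property
    def n_trials(self) -> int:
        return int(self.totals.sum())

    def scaled(self, factor: int) -> "RatingCounts":
        return RatingCounts(n=self.n * int(factor), mu=self.mu)

    def frequencies(self) -> np.ndarray:
        """Empirical P(j, k | i)."""
        return self.n / self.totals[:, None, None]


def trials_to_counts(
    trials: pd.DataFrame,
    m: int | None = None,
    mu: np.ndarray | None = None,
) -> RatingCounts:
    """Aggregate a trial table into a :class:`RatingCounts` tensor.

    Stimulus strengths are taken from ``mu`` when given (so that strengths
    with zero observed trials still raise rather than silently vanish),
    otherwise from the sorted unique values in the table.
    """
    required = {"stimulus", "response", "confidence"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    strengths = np.sort(trials["stimulus"].unique()) if mu is None \
        else np.atleast_1d(np.asarray(mu, dtype=float))
    lev = trials["confidence"].to_numpy()
    if not np.issubdtype(lev.dtype, np.integer):
        if np.any(lev != np.round(lev)):
            raise ValueError("confidence levels must be integers")
        lev = lev.astype(int)
    m_eff = int(lev.max()) if m is None else int(m)
    if lev.min() < 1 or lev.max() > m_eff:
        raise ValueError(f"confidence levels must lie in 1..{m_eff}")
    resp = trials["response"].to_numpy()
    if not np.all(np.isin(resp, [-1, 1])):
        raise ValueError("responses must be coded -1/+1")
    i_idx = np.searchsorted(strengths, trials["stimulus"].to_numpy())
    if np.any(i_idx >= strengths.size) or np.any(
        strengths[np.clip(i_idx, 0, strengths.size - 1)] != trials["stimulus"].to_numpy()
    ):
        raise ValueError("trial stimulus not found in declared strengths")
    n = np.zeros((strengths.size, 2, m_eff), dtype=np.int64)
    np.add.at(n, (i_idx, (resp > 0).astype(int), lev - 1), 1)
    return RatingCounts(n=n, mu=strengths)
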