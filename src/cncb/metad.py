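"""Meta-d' and the M-ratio (standard equal-variance SDT formulation).

Meta-d' is the Type 1 sensitivity that an ideal rater would need to
produce the observed response-conditional confidence distributions,
expressed in d' units.  Following the original formulation, the relative
Type 1 criterion c' = c / d' is preserved in the Type 2 model, and the
m - 1 response-conditional confidence criteria on each side are
estimated jointly with meta-d' by maximum likelihood on the Type 2 count
distributions.  The M-ratio is meta-d' / d'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .data import RatingCounts

__all__ = ["MetaDResult", "fit_metad", "mratio"]


@dataclass(frozen=True)
class MetaDResult:
    """Type 1 and Type 2 sensitivities from one two-stimulus count table."""

    d_prime: float
    criterion_c: float
    meta_d: float
    meta_c: float
    m_ratio: float
    logL: float
    t2_criteria_minus: np.ndarray
    t2_criteria_plus: np.ndarray
    padded: bool

    def __post_init__(self):
        if self.d_prime != 0 and \
                abs(self.m_ratio - self.meta_d / self.d_prime) > 1e-9:
            raise ValueError("m_ratio inconsistent with meta_d / d_prime")


def _type1_sdt(counts: RatingCounts) -> tuple[float, float]:
    """d' and criterion c from the Type 1 margins, with a half-count
    correction for empty cells."""
    n = counts.n
    n_plus = n[:, 1, :].sum(axis=1).astype(float)
    tot = counts.totals.astype(float)
    # stimulus 0 is the 'negative' class, stimulus 1 the 'positive' class
    fa_n, hit_n = n_plus[0], n_plus[1]
    if fa_n in (0.0, tot[0]):
        fa_n += 0.5 if fa_n == 0.0 else -0.5
    if hit_n in (0.0, tot[1]):
        hit_n += 0.5 if hit_n == 0.0 else -0.5
    hr, far = hit_n / tot[1], fa_n / tot[0]
    z_h, z_f = ndtri(hr), ndtri(far)
    return float(z_h - z_f), float(-0.5 * (z_h + z_f))


def _t2_probs(meta_d: float, meta_c: float, t_minus: np.ndarray,
              t_plus: np.ndarray) -> np.ndarray:
    """P(conf = k | stimulus, response) under the meta-d' model.

    Returns shape (2 stimuli, 2 responses, m); stimulus means are
    -/+ meta_d / 2 with unit variance.
    """
    m = t_plus.size + 1
    out = np.empty((2, 2, m))
    for si, mean in enumerate((-meta_d / 2.0, meta_d / 2.0)):
        edges_plus = np.concatenate([[meta_c], t_plus, [np.inf]])
        p_plus = np.diff(ndtr(edges_plus - mean))
        edges_minus = np.concatenate([[-np.inf], t_minus[::-1], [meta_c]])
        p_minus = np.diff(ndtr(edges_minus - mean))[::-1]
        out[si, 1, :] = p_plus / max(p_plus.sum(), 1e-300)
        out[si, 0, :] = p_minus / max(p_minus.sum(), 1e-300)
    return out


def fit_metad(counts: RatingCounts) -> MetaDResult:
    """Fit meta-d' to a two-stimulus rating count table.

    Raises ``ValueError`` when there are not exactly two stimulus classes
    or when d' is undefined (all responses identical).
    """
    if counts.n_stimuli != 2:
        raise ValueError("meta-d' requires exactly two stimulus classes")
    m = counts.m
    d_prime, c = _type1_sdt(counts)
    if d_prime == 0.0:
        raise ValueError("d' is zero; meta-d' is undefined")
    c_rel = c / d_prime

    t2 = counts.n.astype(float).copy()
    padded = bool(np.any(t2 == 0))
    if padded:
        t2 += 1.0 / (2.0 * m)

    def unpack(x):
        meta_d = x[0]
        meta_c = c_rel * meta_d
        t_plus = meta_c + np.cumsum(np.exp(np.clip(x[1:m], -20, 20)))
        t_minus = meta_c - np.cumsum(np.exp(np.clip(x[m:], -20, 20)))
        return meta_d, meta_c, t_minus, t_plus

    def nll(x):
        meta_d, meta_c, t_minus, t_plus = unpack(x)
        p = _t2_probs(meta_d, meta_c, t_minus, t_plus)
        return -float(np.sum(t2 * np.log(np.maximum(p, 1e-12))))

    # spread the confidence criteria to match the pooled rating quantiles
    q = t2.sum(axis=(0, 1))
    cum = np.clip(np.cumsum(q) / q.sum(), 1e-4, 1 - 1e-4)[:-1]
    gaps = np.maximum(np.diff(np.concatenate([[0.0], ndtri(cum) - ndtri(cum[0])])), 0.05)
    x0 = np.concatenate([[d_prime], np.log(gaps), np.log(gaps)])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 200 * x0.size, "fatol": 1e-10,
                            "xatol": 1e-7, "adaptive": True})
    res2 = minimize(nll, res.x, method="L-BFGS-B",
                    options={"ftol": 1e-13, "gtol": 1e-9})
    if res2.fun <= res.fun:
        res = res2
    meta_d, meta_c, t_minus, t_plus = unpack(res.x)
    return MetaDResult(
        d_prime=d_prime,
        criterion_c=c,
        meta_d=float(meta_d),
        meta_c=float(meta_c),
        m_ratio=float(meta_d / d_prime),
        logL=-float(res.fun),
        t2_criteria_minus=t_minus,
        t2_criteria_plus=t_plus,
        padded=padded,
    )


def mratio(counts: RatingCounts) -> float:
    """Convenience wrapper: the M-ratio (meta-d' over d') of a count table."""
    return fit_metad(counts).m_ratio
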