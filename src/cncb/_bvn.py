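"""Standard bivariate normal CDF.

Evaluated through Owen's T function, which gives an exact (machine
precision) expression for the orthant probability at any correlation,
including correlations arbitrarily close to +/-1 where quadrature-based
CDF algorithms lose accuracy.  The identity used is

    Phi2(h, k, rho) = (Phi(h) + Phi(k)) / 2
                      - T(h, a_h) - T(k, a_k) - beta,

with a_h = (k - rho h) / (h sqrt(1 - rho^2)) (a_k symmetric), and
beta = 1/2 when h k < 0 or (h k = 0 and h + k < 0), else 0.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf"]

# limits at h == 0 are continuous; a vanishing offset routes them through
# the generic expression without a special case
_TINY = 1e-300


def bvn_cdf(h, k, rho: float, omr2: float | None = None):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Parameters
    ----------
    h, k : array_like
        Upper limits; broadcast against each other. May be +/-inf.
    rho : float
        Correlation, shared by all (h, k) pairs.
    omr2 : float, optional
        1 - rho**2 computed analytically by the caller when a cancellation-free
        expression is available (e.g. sigma_c**2 / var_w in the CNCB model).

    Returns
    -------
    ndarray or float
        Probabilities clipped to [0, 1].
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    scalar = h.ndim == 0
    h = np.atleast_1d(h)
    k = np.atleast_1d(k)

    if rho == 0.0:
        out = ndtr(h) * ndtr(k)
        return float(out[0]) if scalar else out

    if omr2 is None:
        omr2 = (1.0 - rho) * (1.0 + rho)
    if abs(rho) >= 1.0 or omr2 <= 0.0:
        if rho > 0:
            out = ndtr(np.minimum(h, k))
        else:
            out = np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, 1.0)
        return float(out[0]) if scalar else out

    s = np.sqrt(omr2)
    hh = np.where(h == 0.0, _TINY, h)
    kk = np.where(k == 0.0, _TINY, k)
    all_finite = bool(np.isfinite(hh).all() and np.isfinite(kk).all())
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ah = (kk - rho * hh) / (hh * s)
        ak = (hh - rho * kk) / (kk * s)
    if not all_finite:
        # owens_t(x, +/-inf) is the half-tail; replace non-finite slopes
        # arising from inf/inf with large finite surrogates
        ah = np.nan_to_num(ah, nan=0.0, posinf=1e308, neginf=-1e308)
        ak = np.nan_to_num(ak, nan=0.0, posinf=1e308, neginf=-1e308)
        hh_s = np.clip(hh, -38.0, 38.0)
        kk_s = np.clip(kk, -38.0, 38.0)
    else:
        hh_s, kk_s = hh, kk
    beta = np.where(hh * kk < 0.0, 0.5, 0.0)
    out = 0.5 * (ndtr(hh_s) + ndtr(kk_s)) - owens_t(hh_s, ah) - owens_t(kk_s, ak) - beta

    if not all_finite:
        # infinite limits reduce to univariate margins
        out = np.where(np.isneginf(h) | np.isneginf(k), 0.0, out)
        out = np.where(np.isposinf(h), ndtr(k), out)
        out = np.where(np.isposinf(k) & ~np.isinf(h), ndtr(h), out)
        out = np.where(np.isposinf(h) & np.isposinf(k), 1.0, out)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out
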