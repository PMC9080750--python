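"""Zero-truncated Poisson (ZTP) distribution utilities.

The post-buzz pause is recorded in integer milliseconds and can never be 0,
so the response distribution used throughout this package is the Poisson
distribution conditioned on strictly positive counts:

    P(K = k | lambda) = lambda^k e^{-lambda} / (k! (1 - e^{-lambda})),  k >= 1

with mean lambda / (1 - e^{-lambda}).  All log-scale computations use
``log1p(-exp(-lambda))`` / ``log(-expm1(-lambda))`` forms so they stay
accurate from lambda ~ 1e-10 up to ~1e4.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

__all__ = [
    "ztp_logpmf",
    "ztp_pmf",
    "ztp_mean",
    "ztp_rate_for_mean",
    "ztp_rvs",
]


def _log1mexp(x):
    """log(1 - exp(-x)) for x > 0, numerically stable on both ends."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < np.log(2.0),
        np.log(-np.expm1(-np.where(x < np.log(2.0), x, 1.0))),
        np.log1p(-np.exp(-np.where(x < np.log(2.0), 1.0, x))),
    )
    return out


def ztp_logpmf(k, lam):
    """Log-pmf of the zero-truncated Poisson distribution.

    Parameters
    ----------
    k : int or array-like of int
        Counts; support is k >= 1.
    lam : float or array-like
        Poisson rate of the untruncated parent, lam > 0.

    Returns
    -------
    float or ndarray
        ``k*log(lam) - lam - log(k!) - log(1 - exp(-lam))``.

    Raises
    ------
    ValueError
        If any ``k < 1`` (outside the support) or any ``lam <= 0``.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr < 1):
        raise ValueError("zero-truncated Poisson support is k >= 1")
    if np.any(~np.isfinite(lam_arr)) or np.any(lam_arr <= 0):
        raise ValueError("rate lambda must be positive and finite")
    k_arr = k_arr.astype(float)
    out = (
        k_arr * np.log(lam_arr)
        - lam_arr
        - special.gammaln(k_arr + 1.0)
        - _log1mexp(lam_arr)
    )
    if np.isscalar(k) and np.isscalar(lam):
        return float(out)
    return out


def ztp_pmf(k, lam):
    """Pmf of the zero-truncated Poisson distribution (see :func:`ztp_logpmf`)."""
    return np.exp(ztp_logpmf(k, lam))


def ztp_mean(lam):
    """Mean of the zero-truncated Poisson: lam / (1 - exp(-lam))."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("rate lambda must be positive")
    out = lam_arr / -np.expm1(-lam_arr)
    return float(out) if np.isscalar(lam) else out


def ztp_rate_for_mean(mean):
    """Invert the ZTP mean identity: find lam with lam/(1-exp(-lam)) = mean.

    The mean of a ZTP is always > 1; ``mean`` must be strictly greater than 1.
    For large means the truncation correction is exponentially small and
    lam ~= mean.
    """
    m = float(mean)
    if m <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    if m > 30.0:
        # correction e^{-lam} below double precision relative to m
        return m
    # mean - lam = lam e^{-lam}/(1-e^{-lam}) in (0,1): bracket [m-1, m]
    f = lambda lam: lam / -np.expm1(-lam) - m
    return float(optimize.brentq(f, max(m - 1.0, 1e-12), m, xtol=1e-12, rtol=1e-14))


def ztp_rvs(lam, size=None, rng=None):
    """Draw zero-truncated Poisson variates.

    Two exact samplers are used depending on the rate: for lam >= 1,
    rejection from the untruncated Poisson (zeros are redrawn; acceptance
    probability 1 - e^{-lam} >= 0.63); for lam < 1, inversion of the
    truncated CDF over k >= 1, where the support is effectively tiny.

    Parameters
    ----------
    lam : float or array-like
        Rate(s) of the untruncated parent; positive.
    size : int or tuple, optional
        Output shape; defaults to the broadcast shape of ``lam``.
    rng : numpy.random.Generator, optional
        Source of randomness; a fresh default generator if omitted.

    Returns
    -------
    ndarray of int
        Draws with every value >= 1.
    """
    if rng is None:
        rng = np.random.default_rng()
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0) or np.any(~np.isfinite(lam_arr)):
        raise ValueError("rate lambda must be positive and finite")
    if size is None:
        size = lam_arr.shape
    lam_b = np.broadcast_to(lam_arr, size).copy() if size != () else lam_arr
    out = np.empty(size, dtype=np.int64)
    flat_lam = np.atleast_1d(lam_b).ravel()
    flat_out = np.atleast_1d(out).ravel()

    big = flat_lam >= 1.0
    if np.any(big):
        lam_big = flat_lam[big]
        draws = rng.poisson(lam_big)
        zero = draws == 0
        while np.any(zero):
            draws[zero] = rng.poisson(lam_big[zero])
            zero = draws == 0
        flat_out[big] = draws
    if np.any(~big):
        lam_small = flat_lam[~big]
        u = rng.uniform(size=lam_small.shape)
        # inverse CDF over k>=1: walk the pmf; at lam<1 the needed k is tiny
        target = u * -np.expm1(-lam_small)  # u * P(K>=1) on parent scale
        k = np.ones(lam_small.shape, dtype=np.int64)
        term = lam_small * np.exp(-lam_small)  # parent pmf at k=1
        cum = term.copy()
        unfinished = cum < target
        while np.any(unfinished):
            k[unfinished] += 1
            term[unfinished] *= lam_small[unfinished] / k[unfinished]
            cum[unfinished] += term[unfinished]
            unfinished = cum < target
        flat_out[~big] = k
    if np.ndim(out) == 0:
        return out[()]
    return out
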