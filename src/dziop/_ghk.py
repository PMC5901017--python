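"""Numba kernels for the GHK (Geweke–Hajivassiliou–Keane) simulator.

The trivariate rectangle probability P(l_k < eps_k <= u_k, k=1..3) for a
standard trivariate normal with correlation matrix Omega is simulated by
recursive conditioning through the Cholesky factor L of Omega: each
dimension is sampled from its conditional truncated normal via inverse-CDF
transforms of (quasi-)uniform draws, and the product of the conditional
band probabilities is averaged over draws.

The recursion is split into three stage kernels so that a likelihood
evaluator can cache the intermediate truncated draws: stage 1 depends only
on the participation index, stage 2 additionally on the misreporting index
and the (2,1) block of L, stage 3 on everything.  Draws are common random
numbers: they are generated once per fit and reused at every parameter
value, which keeps the simulated objective smooth in the parameters.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_QEPS = 1e-15


@njit(cache=True, fastmath=True)
def _phi(x):
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True, fastmath=True)
def _phi_inv(p):
    """Standard normal quantile (Wichura's PPND16, ~1e-15 accurate)."""
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
                    + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
                  + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
                + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
                    + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
                  + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
                + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    if q < 0.0:
        r = p
    else:
        r = 1.0 - p
    if r <= 0.0:
        return -38.5 if q < 0.0 else 38.5
    r = math.sqrt(-math.log(r))
    if r <= 5.0:
        r = r - 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
                    + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
                  + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
                + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
                    + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
                  + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
                + 2.05319162663775882187e0) * r + 1.0)
    else:
        r = r - 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
                    + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
                  + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
                + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
                    + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
                  + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
                + 5.99832206555887937690e-1) * r + 1.0)
    val = num / den
    return -val if q < 0.0 else val


@njit(cache=True, fastmath=True)
def ghk_stage1(lo, hi, u1):
    """First-dimension band probabilities and truncated draws.

    Returns (p1, z1): p1[i] = P(lo_i < eta1 <= hi_i), z1[i, d] the draw of
    eta1 conditional on the band, for quasi-uniform u1[d].
    """
    n = lo.shape[0]
    D = u1.shape[0]
    p1 = np.empty(n)
    z1 = np.empty((n, D))
    for i in range(n):
        qlo = 0.0 if lo[i] == -np.inf else _phi(lo[i])
        qhi = 1.0 if hi[i] == np.inf else _phi(hi[i])
        p = qhi - qlo
        p1[i] = p
        for d in range(D):
            q = qlo + u1[d] * p
            if q < _QEPS:
                q = _QEPS
            elif q > 1.0 - _QEPS:
                q = 1.0 - _QEPS
            z1[i, d] = _phi_inv(q)
    return p1, z1


@njit(cache=True, fastmath=True)
def ghk_stage2(lo, hi, z1, u2, L21, L22):
    """Second-dimension conditional band probabilities and truncated draws."""
    n = lo.shape[0]
    D = u2.shape[0]
    p2 = np.empty((n, D))
    z2 = np.empty((n, D))
    for i in range(n):
        loi = lo[i]
        hii = hi[i]
        for d in range(D):
            m = L21 * z1[i, d]
            qlo = 0.0 if loi == -np.inf else _phi((loi - m) / L22)
            qhi = 1.0 if hii == np.inf else _phi((hii - m) / L22)
            p2[i, d] = qhi - qlo
            q = qlo + u2[d] * (qhi - qlo)
            if q < _QEPS:
                q = _QEPS
            elif q > 1.0 - _QEPS:
                q = 1.0 - _QEPS
            z2[i, d] = _phi_inv(q)
    return p2, z2


@njit(cache=True, fastmath=True)
def ghk_stage3(lo, hi, z1, z2, p2, L31, L32, L33):
    """Average over draws of p2 * (third-dimension conditional band prob).

    The returned vector multiplied by p1 is the GHK rectangle probability.
    """
    n = lo.shape[0]
    D = z1.shape[1]
    out = np.empty(n)
    for i in range(n):
        loi = lo[i]
        hii = hi[i]
        acc = 0.0
        for d in range(D):
            m = L31 * z1[i, d] + L32 * z2[i, d]
            qlo = 0.0 if loi == -np.inf else _phi((loi - m) / L33)
            qhi = 1.0 if hii == np.inf else _phi((hii - m) / L33)
            acc += p2[i, d] * (qhi - qlo)
        out[i] = acc / D
    return out


def ghk_rectangle(lower, upper, chol, u1, u2):
    """GHK estimate of trivariate rectangle probabilities, vectorised over rows.

    lower/upper: (3, n) arrays of per-row bounds (+-inf allowed);
    chol: lower Cholesky factor of the 3x3 correlation matrix;
    u1, u2: (D,) quasi-uniform draws shared across rows.
    """
    p1, z1 = ghk_stage1(lower[0], upper[0], u1)
    p2, z2 = ghk_stage2(lower[1], upper[1], z1, u2, chol[1, 0], chol[1, 1])
    s3 = ghk_stage3(lower[2], upper[2], z1, z2, p2,
                    chol[2, 0], chol[2, 1], chol[2, 2])
    return p1 * s3
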