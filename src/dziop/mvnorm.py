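"""Gaussian probability engine: bivariate/trivariate CDFs, GHK rectangles.

All the model's category probabilities reduce to rectangle probabilities of
a standard (bi/tri)variate normal.  Three routes are provided:

* ``normal_cdf2`` — deterministic bivariate CDF (a port of Genz's
  Drezner–Wesolowsky/Gauss–Legendre algorithm, absolute error well below
  1e-10), vectorised over the limits for a scalar correlation;
* ``normal_cdf3`` — trivariate CDF, either by adaptive quadrature of the
  conditional bivariate CDF (deterministic) or by the GHK simulator;
* ``ghk_rect_prob`` — the GHK simulated rectangle probability with
  scrambled Halton draws and antithetic pairing.

``signed_region_prob`` is the single audited primitive behind every model
formula: P(s_k * eps_k <= a_k, k in region) for signs s_k in {-1, +1},
computed by flipping the corresponding rows/columns of the correlation
matrix (corr'_kl = s_k s_l corr_kl).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

from ._ghk import ghk_rectangle

__all__ = [
    "normal_cdf2",
    "normal_cdf3",
    "ghk_rect_prob",
    "signed_region_prob",
    "halton_uniforms",
]

_TWOPI = 2.0 * math.pi

# Gauss-Legendre half-rules used by the Genz bivariate algorithm
_GL6_W = np.array([0.1713244923791705, 0.3607615730481384, 0.4679139345726904])
_GL6_X = np.array([0.9324695142031522, 0.6612093864662647, 0.2386191860831970])
_GL12_W = np.array([0.04717533638651177, 0.1069393259953183, 0.1600783285433464,
                    0.2031674267230659, 0.2334925365383547, 0.2491470458134029])
_GL12_X = np.array([0.9815606342467191, 0.9041172563704750, 0.7699026741943050,
                    0.5873179542866171, 0.3678314989981802, 0.1252334085114692])
_GL20_W = np.array([0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
                    0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
                    0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
                    0.1527533871307259])
_GL20_X = np.array([0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
                    0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
                    0.5108670019508271, 0.3737060887154196, 0.2277858511416451,
                    0.07652652113349733])


def _bvnu_finite(h, k, r):
    """Genz's algorithm for P(X > h, Y > k), finite h, k; scalar r."""
    if r == 0.0:
        return ndtr(-h) * ndtr(-k)
    if abs(r) < 0.3:
        w, x = _GL6_W, _GL6_X
    elif abs(r) < 0.75:
        w, x = _GL12_W, _GL12_X
    else:
        w, x = _GL20_W, _GL20_X
    w = np.concatenate([w, w])
    x = np.concatenate([1.0 - x, 1.0 + x])

    hk = h * k
    if abs(r) < 0.925:
        hs = (h * h + k * k) / 2.0
        asr = math.asin(r) / 2.0
        sn = np.sin(asr * x)  # (2m,)
        # exponent: (sn*hk - hs)/(1 - sn^2), summed against weights
        expo = (sn[:, None] * hk[None, :] - hs[None, :]) / (1.0 - sn[:, None] ** 2)
        bvn = np.einsum("i,ij->j", w, np.exp(expo))
        return bvn * asr / _TWOPI + ndtr(-h) * ndtr(-k)

    # |r| >= 0.925: Genz's expansion about r = +-1
    if r < 0.0:
        k = -k
        hk = -hk
    bvn = np.zeros_like(h)
    if abs(r) < 1.0:
        a_s = (1.0 - r) * (1.0 + r)
        a = math.sqrt(a_s)
        bs = (h - k) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr0 = -(bs / a_s + hk) / 2.0
        m0 = asr0 > -100.0
        bvn = np.where(
            m0,
            a * np.exp(np.where(m0, asr0, 0.0))
            * (1.0 - c * (bs - a_s) * (1.0 - d * bs / 5.0) / 3.0
               + c * d * a_s * a_s / 5.0),
            0.0,
        )
        m1 = -hk < 100.0
        b = np.sqrt(bs)
        sp = math.sqrt(_TWOPI) * ndtr(-b / a)
        bvn = bvn - np.where(
            m1,
            np.exp(np.where(m1, -hk / 2.0, 0.0)) * sp * b
            * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0),
            0.0,
        )
        a2 = a / 2.0
        for sgn in (-1.0, 1.0):
            for wi, xi in zip(w[: len(w) // 2], x[len(x) // 2:] - 1.0):
                xs = (a2 * (sgn * xi + 1.0)) ** 2
                rs = math.sqrt(1.0 - xs)
                asr = -(bs / xs + hk) / 2.0
                mm = asr > -100.0
                term = (np.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
                        - (1.0 + c * xs * (1.0 + d * xs)))
                bvn = bvn + np.where(mm, a2 * wi * np.exp(np.where(mm, asr, 0.0)) * term, 0.0)
        bvn = -bvn / _TWOPI
    if r > 0.0:
        bvn = bvn + ndtr(-np.maximum(h, k))
    else:
        bvn = -bvn + np.maximum(0.0, ndtr(-h) - ndtr(-k))
    return bvn


def bvnu(h, k, r):
    """Upper-orthant P(X > h, Y > k) for standard bivariate normal, corr r.

    ``h`` and ``k`` broadcast; ``r`` is scalar with |r| < 1.  Infinite
    limits are handled by reduction to the univariate CDF.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    out = np.empty(h.shape, dtype=float)
    hinf_p = h == np.inf
    kinf_p = k == np.inf
    hinf_m = h == -np.inf
    kinf_m = k == -np.inf
    out[hinf_p | kinf_p] = 0.0
    both_m = hinf_m & kinf_m
    out[both_m] = 1.0
    only_h = hinf_m & ~kinf_m & ~kinf_p
    out[only_h] = ndtr(-k[only_h])
    only_k = kinf_m & ~hinf_m & ~hinf_p
    out[only_k] = ndtr(-h[only_k])
    fin = ~(hinf_p | kinf_p | hinf_m | kinf_m)
    if np.any(fin):
        out[fin] = np.clip(_bvnu_finite(h[fin], k[fin], float(r)), 0.0, 1.0)
    return out


def normal_cdf2(a, b, rho):
    """P(Z1 <= a, Z2 <= b) for a standard bivariate normal with correlation rho.

    Deterministic with absolute error <= 1e-10; ``a``/``b`` may be arrays
    (broadcast) or +-inf; ``rho`` must satisfy |rho| < 1.
    """
    rho = float(rho)
    if not abs(rho) < 1.0:
        raise ValueError(f"correlation must satisfy |rho| < 1, got {rho}")
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    res = bvnu(-a_arr, -b_arr, rho)
    if np.isscalar(a) and np.isscalar(b):
        return float(res)
    return res


def _validate_corr3(corr):
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (3, 3):
        raise ValueError("corr must be a 3x3 correlation matrix")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("corr must have unit diagonal")
    if not np.allclose(corr, corr.T):
        raise ValueError("corr must be symmetric")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        eigs = np.linalg.eigvalsh(corr)
        raise ValueError(
            "correlation matrix is not positive definite "
            f"(eigenvalues {np.round(eigs, 6)})"
        ) from exc
    return corr, chol


def halton_uniforms(n_draws, seed):
    """Scrambled 2-d Halton points (bases 2, 3) with antithetic pairing.

    Returns (u1, u2), each of length ``n_draws``; the second half of each
    is the antithetic complement of the first half.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    base = (n_draws + 1) // 2
    eng = qmc.Halton(d=2, scramble=True, seed=int(seed))
    u = eng.random(base)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    full = np.vstack([u, 1.0 - u])[:n_draws]
    return np.ascontiguousarray(full[:, 0]), np.ascontiguousarray(full[:, 1])


def ghk_rect_prob(upper_limits, corr, n_draws=500, seed=0, lower_limits=None):
    """GHK simulated P(l_k < Z_k <= u_k, k=1..3), deterministic given seed.

    Uses scrambled Halton draws (bases 2 and 3) with antithetic pairing;
    the simulation standard error decays faster than n_draws^(-1/2).
    """
    corr, chol = _validate_corr3(corr)
    upper = np.asarray(upper_limits, dtype=float).reshape(3)
    if lower_limits is None:
        lower = np.full(3, -np.inf)
    else:
        lower = np.asarray(lower_limits, dtype=float).reshape(3)
    u1, u2 = halton_uniforms(n_draws, seed)
    p = ghk_rectangle(lower[:, None], upper[:, None], chol, u1, u2)
    return float(p[0])


def _cdf3_quadrature(upper, corr):
    """Trivariate CDF by adaptive quadrature over the conditioning variable."""
    a = np.asarray(upper, dtype=float)
    if np.any(a == -np.inf):
        return 0.0
    finite = a < np.inf
    nfin = int(finite.sum())
    if nfin == 0:
        return 1.0
    idx = np.where(finite)[0]
    if nfin == 1:
        return float(ndtr(a[idx[0]]))
    if nfin == 2:
        i, j = idx
        return float(normal_cdf2(a[i], a[j], corr[i, j]))
    # condition on the third variable
    r13, r23, r12 = corr[0, 2], corr[1, 2], corr[0, 1]
    s1 = math.sqrt(1.0 - r13 * r13)
    s2 = math.sqrt(1.0 - r23 * r23)
    r12_3 = np.clip((r12 - r13 * r23) / (s1 * s2), -1.0 + 1e-14, 1.0 - 1e-14)

    def integrand(t):
        return (math.exp(-0.5 * t * t) / math.sqrt(_TWOPI)
                * float(normal_cdf2((a[0] - r13 * t) / s1,
                                    (a[1] - r23 * t) / s2, r12_3)))

    lo = -38.0
    hi = min(float(a[2]), 38.0)
    if hi <= lo:
        return 0.0
    val, _ = integrate.quad(integrand, lo, hi, epsabs=1e-12, epsrel=1e-10,
                            limit=200)
    return float(min(max(val, 0.0), 1.0))


def normal_cdf3(upper_limits, corr, method="quadrature", n_draws=500, seed=0):
    """P(Z1 <= a1, Z2 <= a2, Z3 <= a3) for a standard trivariate normal.

    ``method='quadrature'`` integrates the conditional bivariate CDF over
    the third variable (deterministic; reduces exactly to ``normal_cdf2``
    when one limit is +inf).  ``method='ghk'`` uses the simulator.
    """
    corr, _ = _validate_corr3(corr)
    if method == "quadrature":
        return _cdf3_quadrature(upper_limits, corr)
    if method == "ghk":
        return ghk_rect_prob(upper_limits, corr, n_draws=n_draws, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def signed_region_prob(signs, limits, corr=None, method="quadrature",
                       n_draws=500, seed=0):
    """P(s_k * eps_k <= a_k for k in the region), eps ~ N(0, corr).

    The general signed-region primitive: negating an argument's sign flips
    that dimension, which negates the correlations involving it
    (corr'_kl = s_k s_l corr_kl).  Supports 1-3 dimensions; ``corr`` is the
    correlation matrix of the *unsigned* eps (ignored in one dimension).
    """
    signs = np.asarray(signs, dtype=float).ravel()
    limits = np.asarray(limits, dtype=float).ravel()
    if signs.shape != limits.shape or signs.size not in (1, 2, 3):
        raise ValueError("signs and limits must both have length 1, 2 or 3")
    if not np.all(np.abs(signs) == 1.0):
        raise ValueError("signs must be +-1")
    d = signs.size
    if d == 1:
        return float(ndtr(limits[0])) if np.isfinite(limits[0]) else (
            1.0 if limits[0] > 0 else 0.0)
    corr = np.asarray(corr, dtype=float)
    flipped = corr * np.outer(signs, signs)
    np.fill_diagonal(flipped, 1.0)
    if d == 2:
        return float(normal_cdf2(limits[0], limits[1], flipped[0, 1]))
    return normal_cdf3(limits, flipped, method=method, n_draws=n_draws,
                       seed=seed)


# ---------------------------------------------------------------------------
# vectorised region probabilities used by the model likelihoods

def _gl_nodes(n_nodes):
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    return x, w


#: integration range for the conditioning variable; phi(8.5) ~ 1e-17
_T_TRUNC = 8.5
_INV_SQRT_2PI = 1.0 / math.sqrt(_TWOPI)


def tri_lower2_band(l1, l2, lo3, hi3, rho_rm, rho_ry, rho_my, n_nodes=16,
                    panel_width=2.5):
    """P(eps1 > l1, eps2 > l2, lo3 < eps3 <= hi3), vectorised over rows.

    Deterministic composite Gauss–Legendre quadrature of phi(t) times the
    conditional bivariate upper-orthant probability over the third
    variable: each row's (truncated) band is split into panels at most
    ``panel_width`` wide carrying ``n_nodes`` nodes each, which holds the
    absolute error near machine precision even for wide bands and strong
    correlations.  ``panel_width=None`` uses a single panel (cheaper,
    ~1e-6 worst case; adequate for finite-difference derivatives).
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    lo3 = np.asarray(lo3, dtype=float)
    hi3 = np.asarray(hi3, dtype=float)
    s1 = math.sqrt(1.0 - rho_ry * rho_ry)
    s2 = math.sqrt(1.0 - rho_my * rho_my)
    r12_3 = float(np.clip((rho_rm - rho_ry * rho_my) / (s1 * s2),
                          -1.0 + 1e-14, 1.0 - 1e-14))
    a = np.maximum(lo3, -_T_TRUNC)
    b = np.minimum(hi3, _T_TRUNC)
    shape = np.broadcast(l1, l2, a, b).shape
    l1, l2, a, b = np.broadcast_arrays(l1, l2, a, b)
    width = np.maximum(b - a, 0.0)
    x, w = _gl_nodes(n_nodes)
    out = np.zeros(shape, dtype=float)
    if panel_width is None:
        panels = np.ones(shape, dtype=int)
    else:
        panels = np.maximum(np.ceil(width / panel_width).astype(int), 1)
    for P in np.unique(panels):
        idx = panels == P
        aP, bP, l1P, l2P = a[idx], b[idx], l1[idx], l2[idx]
        step = (bP - aP) / P
        acc = np.zeros(aP.shape, dtype=float)
        for k in range(P):
            mid = aP + (k + 0.5) * step
            half = 0.5 * step
            for xq, wq in zip(x, w):
                t = mid + half * xq
                dens = _INV_SQRT_2PI * np.exp(-0.5 * t * t)
                acc += wq * half * dens * bvnu((l1P - rho_ry * t) / s1,
                                               (l2P - rho_my * t) / s2,
                                               r12_3)
        out[idx] = acc
    return np.clip(out, 0.0, 1.0)
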