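"""Maximum (simulated) likelihood estimation for the zero-inflated OP family.

All variants are estimated by quasi-Newton (BFGS) maximization of the
log-likelihood in an unconstrained parameterization:

* thresholds: mu_1 = exp(c_1), mu_j = mu_{j-1} + exp(c_j), so any real
  vector c maps to a strictly ordered threshold vector;
* correlations: hyperbolic-tangent transforms of partial correlations in
  the fixed elimination order (rm, ry, my|r), bounded at |.| <= 0.99,
  which guarantees a positive-definite Omega3 for any real input;
* coefficients: unrestricted.

The DZIOPC likelihood involves trivariate normal rectangle probabilities
which are simulated with the GHK algorithm using scrambled Halton draws
(bases 2 and 3, antithetic pairing).  Draws are generated once per fit and
held fixed across optimizer iterations (common random numbers), so the
simulated objective is a smooth deterministic function of the parameters.
Gradients are central finite differences with step 1e-5 * (1 + |theta_k|).

Robust ("sandwich") covariances H^-1 (sum_i g_i g_i') H^-1 are computed
from finite-difference per-row scores and Hessian, then mapped to the
reported parameterization (coefficients, thresholds, correlations) through
the Jacobian of the back-transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .model_core import (PROB_FLOOR, ObservationSet, ParameterSet,
                         _check_dims, _indices, _is_correlated,
                         _row_thresholds, _uses_misreporting,
                         _uses_participation, category_probs)
from .mvnorm import bvnu, halton_uniforms, tri_lower2_band
from ._ghk import ghk_stage1, ghk_stage2, ghk_stage3

__all__ = [
    "FitResult",
    "LRTestResult",
    "loglik",
    "starting_values",
    "fit",
    "sandwich_cov",
    "lr_independence_test",
]

RHO_BOUND = 0.99
GRAD_STEP = 1e-5
HESS_STEP = 1e-4
#: correlations within this distance of the bound are flagged in FitResult
RHO_EDGE = 0.95


# ---------------------------------------------------------------------------
# parameter packing

class ParamTransform:
    """Maps between the unconstrained vector theta and a ParameterSet."""

    def __init__(self, variant, kr, km, ky, J, kz=0, fix_rho=False):
        self.variant = variant
        self.kr = kr if _uses_participation(variant) else 0
        self.km = km if _uses_misreporting(variant) else 0
        self.ky = ky
        self.J = J
        self.kz = kz if variant == "GOP" else 0
        if fix_rho or not _is_correlated(variant):
            self.n_rho = 0
        else:
            self.n_rho = 3 if variant == "DZIOPC" else 1
        sizes = [self.kr, self.km, self.ky, J - 1,
                 (J - 1) * self.kz, self.n_rho]
        edges = np.concatenate([[0], np.cumsum(sizes)])
        self.slices = [slice(int(a), int(b)) for a, b in zip(edges, edges[1:])]
        self.n_params = int(edges[-1])

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        s = self.slices
        beta_r = theta[s[0]]
        beta_m = theta[s[1]]
        beta_y = theta[s[2]]
        mu = np.cumsum(np.exp(np.clip(theta[s[3]], -300, 300)))
        gamma = (theta[s[4]].reshape(self.J - 1, self.kz)
                 if self.kz else None)
        rho_rm = rho_ry = rho_my = 0.0
        eta = theta[s[5]]
        if self.n_rho == 1:
            rho_ry = RHO_BOUND * np.tanh(eta[0])
        elif self.n_rho == 3:
            t1, t2, t3 = RHO_BOUND * np.tanh(eta)
            rho_rm = t1
            rho_ry = t2
            rho_my = t1 * t2 + t3 * np.sqrt((1 - t1 * t1) * (1 - t2 * t2))
        return ParameterSet(beta_r=beta_r, beta_m=beta_m, beta_y=beta_y,
                            mu=mu, rho_rm=rho_rm, rho_ry=rho_ry,
                            rho_my=rho_my, variant=self.variant, gamma=gamma)

    def pack(self, params: ParameterSet):
        steps = np.concatenate([[params.mu[0]], np.diff(params.mu)])
        c = np.log(np.maximum(steps, 1e-8))
        parts = [params.beta_r[: self.kr], params.beta_m[: self.km],
                 params.beta_y, c]
        if self.kz:
            g = (params.gamma if params.gamma is not None
                 else np.zeros((self.J - 1, self.kz)))
            parts.append(g.ravel())
        if self.n_rho == 1:
            parts.append(np.arctanh(
                np.clip([params.rho_ry / RHO_BOUND], -0.9999, 0.9999)))
        elif self.n_rho == 3:
            t1 = params.rho_rm
            t2 = params.rho_ry
            denom = np.sqrt(max((1 - t1 * t1) * (1 - t2 * t2), 1e-12))
            t3 = (params.rho_my - t1 * t2) / denom
            t = np.clip(np.array([t1, t2, t3]) / RHO_BOUND, -0.9999, 0.9999)
            parts.append(np.arctanh(t))
        return np.concatenate([np.atleast_1d(p) for p in parts])

    def reported(self, theta):
        """Constrained (reported) parameter vector for a given theta."""
        p = self.unpack(theta)
        parts = [p.beta_r, p.beta_m, p.beta_y, p.mu]
        if self.kz:
            parts.append(p.gamma.ravel())
        if self.n_rho == 1:
            parts.append([p.rho_ry])
        elif self.n_rho == 3:
            parts.append([p.rho_rm, p.rho_ry, p.rho_my])
        return np.concatenate([np.atleast_1d(x) for x in parts])

    def names(self, obs: ObservationSet):
        out = []
        if self.kr:
            out += [f"r:{c}" for c in obs.names_r]
        if self.km:
            out += [f"m:{c}" for c in obs.names_m]
        out += [f"y:{c}" for c in obs.names_y]
        out += [f"mu_{j}" for j in range(1, self.J)]
        if self.kz:
            out += [f"thr{j}:{c}" for j in range(1, self.J)
                    for c in obs.names_thresh]
        if self.n_rho == 1:
            out += ["rho_ry"]
        elif self.n_rho == 3:
            out += ["rho_rm", "rho_ry", "rho_my"]
        return out

    def reported_jacobian(self, theta, step=1e-6):
        theta = np.asarray(theta, dtype=float)
        cols = []
        for k in range(theta.size):
            h = step * (1.0 + abs(theta[k]))
            tp = theta.copy()
            tp[k] += h
            tm = theta.copy()
            tm[k] -= h
            cols.append((self.reported(tp) - self.reported(tm)) / (2 * h))
        return np.column_stack(cols)


def transform_for(obs: ObservationSet, variant: str, fix_rho=False):
    return ParamTransform(variant, obs.Xr.shape[1], obs.Xm.shape[1],
                          obs.Xy.shape[1], obs.J, obs.Z_thresh.shape[1],
                          fix_rho=fix_rho)


# ---------------------------------------------------------------------------
# likelihood evaluators

def _observed_band_edges(y, J, mu_rows, ay):
    """Per-row (lo, hi) limits of ey for the *observed* category (y >= 1);
    zero rows get the complement band (-ay, inf) of positive consumption."""
    n = y.shape[0]
    cuts = np.column_stack([np.zeros(n), mu_rows])
    lo = np.where(y == 0, -ay, cuts[np.arange(n), np.maximum(y - 1, 0)] - ay)
    hi = np.where(y == 0, np.inf,
                  np.where(y < J, cuts[np.arange(n), np.minimum(y, J - 1)] - ay,
                           np.inf))
    # y == J rows: lo is mu_{J-1} - ay
    topmask = y == J
    lo = np.where(topmask, cuts[:, J - 1] - ay, lo)
    return lo, hi


class AnalyticEvaluator:
    """Per-row log-likelihood for variants with closed-form probabilities.

    Also provides the deterministic-quadrature route for DZIOPC, used for
    pre-solves and covariance computations.
    """

    def __init__(self, obs: ObservationSet, transform: ParamTransform,
                 n_nodes=16, panel_width=None):
        self.obs = obs
        self.t = transform
        self.n_nodes = n_nodes
        # single-panel quadrature by default: ~1e-6 worst-case accuracy,
        # ample for optimization and finite-difference derivatives
        self.panel_width = panel_width

    def loglik_vec(self, theta):
        obs = self.obs
        p = self.t.unpack(theta)
        v = p.variant
        y = obs.y
        J = obs.J
        ar, am, ay = _indices(p, obs)
        mu_rows = np.asarray(_row_thresholds(p, obs))
        lo, hi = _observed_band_edges(y, J, mu_rows, ay)
        zero = y == 0

        if v in ("OP", "GOP"):
            band = np.where(zero, ndtr(-ay), ndtr(hi) - ndtr(lo))
            prob = np.where(zero, band, band)
        elif v == "ZIOP":
            band = ndtr(hi) - ndtr(lo)
            prob = np.where(zero,
                            ndtr(-ar) + ndtr(ar) * ndtr(-ay),
                            ndtr(ar) * band)
        elif v == "ZIOPC":
            rect = bvnu(-ar, lo, p.rho_ry) - np.where(
                hi == np.inf, 0.0, bvnu(-ar, hi, p.rho_ry))
            prob = np.where(zero, 1.0 - rect, rect)
        elif v == "DZIOP":
            pr, pm = ndtr(ar), ndtr(am)
            band = ndtr(hi) - ndtr(lo)
            prob = np.where(
                zero,
                ndtr(-ar) + pr * ndtr(-am) + pr * pm * ndtr(-ay),
                pr * pm * band)
        elif v == "DZIOPC":
            rect = tri_lower2_band(-ar, -am, lo, hi, p.rho_rm, p.rho_ry,
                                   p.rho_my, n_nodes=self.n_nodes,
                                   panel_width=self.panel_width)
            prob = np.where(zero, 1.0 - rect, rect)
        else:  # pragma: no cover
            raise ValueError(v)
        return np.log(np.maximum(prob, PROB_FLOOR))

    def loglik(self, theta):
        return float(self.loglik_vec(theta).sum())


class GhkEvaluator:
    """Simulated DZIOPC log-likelihood with stage-level caching.

    The GHK recursion is split so that perturbing only consumption-side
    parameters (beta_y, thresholds, the two consumption correlations)
    reuses the cached truncated draws of the first two dimensions, which
    makes finite-difference gradients far cheaper.
    """

    def __init__(self, obs: ObservationSet, transform: ParamTransform,
                 n_draws=500, seed=0):
        self.obs = obs
        self.t = transform
        self.n_draws = int(n_draws)
        self.seed = int(seed)
        self.u1, self.u2 = halton_uniforms(self.n_draws, self.seed)
        self._c1 = {}
        self._c2 = {}

    def _cache_get(self, cache, key, builder, maxlen=4):
        if key not in cache:
            if len(cache) >= maxlen:
                cache.pop(next(iter(cache)))
            cache[key] = builder()
        return cache[key]

    def loglik_vec(self, theta):
        obs = self.obs
        p = self.t.unpack(theta)
        y = obs.y
        J = obs.J
        ar, am, ay = _indices(p, obs)
        chol = np.linalg.cholesky(p.omega3())
        lo, hi = _observed_band_edges(y, J, np.broadcast_to(p.mu, (obs.n, J - 1)),
                                      ay)
        k1 = ar.tobytes()
        p1, z1 = self._cache_get(
            self._c1, k1,
            lambda: ghk_stage1(-ar, np.full(obs.n, np.inf), self.u1))
        k2 = (k1, am.tobytes(), float(chol[1, 0]))
        p2, z2 = self._cache_get(
            self._c2, k2,
            lambda: ghk_stage2(-am, np.full(obs.n, np.inf), z1, self.u2,
                               chol[1, 0], chol[1, 1]))
        s3 = ghk_stage3(np.ascontiguousarray(lo), np.ascontiguousarray(hi),
                        z1, z2, p2, chol[2, 0], chol[2, 1], chol[2, 2])
        rect = p1 * s3
        prob = np.where(y == 0, 1.0 - rect, rect)
        return np.log(np.maximum(prob, PROB_FLOOR))

    def loglik(self, theta):
        return float(self.loglik_vec(theta).sum())


def _evaluator(obs, transform, variant, n_draws, seed, engine="auto"):
    if variant == "DZIOPC" and engine in ("auto", "ghk"):
        return GhkEvaluator(obs, transform, n_draws=n_draws, seed=seed)
    return AnalyticEvaluator(obs, transform)


# ---------------------------------------------------------------------------
# finite differences

def _fd_gradient(f, theta, step=GRAD_STEP):
    theta = np.asarray(theta, dtype=float)
    g = np.empty_like(theta)
    for k in range(theta.size):
        h = step * (1.0 + abs(theta[k]))
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        g[k] = (f(tp) - f(tm)) / (2.0 * h)
    return g


def _fd_hessian(f, theta, step=HESS_STEP):
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    h = step * (1.0 + np.abs(theta))
    H = np.empty((p, p))
    f0 = f(theta)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        tp = theta.copy()
        tp[i] += h[i]
        tm = theta.copy()
        tm[i] -= h[i]
        fp[i] = f(tp)
        fm[i] = f(tm)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            tpp = theta.copy()
            tpp[[i, j]] += [h[i], h[j]]
            tpm = theta.copy()
            tpm[i] += h[i]
            tpm[j] -= h[j]
            tmp = theta.copy()
            tmp[i] -= h[i]
            tmp[j] += h[j]
            tmm = theta.copy()
            tmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = ((f(tpp) - f(tpm) - f(tmp) + f(tmm))
                                 / (4.0 * h[i] * h[j]))
    return H


def _fd_scores(loglik_vec, theta, step=GRAD_STEP):
    theta = np.asarray(theta, dtype=float)
    n = loglik_vec(theta).size
    G = np.empty((n, theta.size))
    for k in range(theta.size):
        h = step * (1.0 + abs(theta[k]))
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        G[:, k] = (loglik_vec(tp) - loglik_vec(tm)) / (2.0 * h)
    return G


# ---------------------------------------------------------------------------
# results

@dataclass
class FitResult:
    """Estimates and diagnostics from one maximum-likelihood fit."""

    params: ParameterSet
    loglik: float
    param_names: list
    estimates: np.ndarray            # reported parameterization
    cov_robust: np.ndarray | None    # sandwich, reported parameterization
    cov_hessian: np.ndarray | None   # inverse negative Hessian, reported
    gradient_norm: float
    n_iterations: int
    converged: bool
    n_obs: int
    variant: str
    seed: int | None = None
    n_draws: int | None = None
    rho_near_boundary: list = field(default_factory=list)
    theta: np.ndarray | None = None            # unconstrained optimum
    cov_unconstrained: np.ndarray | None = None
    cov_hessian_unconstrained: np.ndarray | None = None
    transform: ParamTransform | None = None

    @property
    def se_robust(self):
        if self.cov_robust is None:
            return None
        return np.sqrt(np.maximum(np.diag(self.cov_robust), 0.0))

    @property
    def se_hessian(self):
        if self.cov_hessian is None:
            return None
        return np.sqrt(np.maximum(np.diag(self.cov_hessian), 0.0))

    @property
    def aic(self):
        return 2.0 * len(self.estimates) - 2.0 * self.loglik

    def to_dict(self):
        d = {
            "variant": self.variant,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "gradient_norm": float(self.gradient_norm),
            "param_names": list(self.param_names),
            "estimates": np.asarray(self.estimates).tolist(),
            "seed": self.seed,
            "n_draws": self.n_draws,
            "rho_near_boundary": list(self.rho_near_boundary),
        }
        if self.cov_robust is not None:
            d["se_robust"] = self.se_robust.tolist()
        if self.cov_hessian is not None:
            d["se_hessian"] = self.se_hessian.tolist()
        return d


@dataclass
class LRTestResult:
    """Likelihood-ratio test of error independence (Omega3 = I3)."""

    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# operations

def loglik(params: ParameterSet, obs: ObservationSet, method="auto",
           n_draws=500, seed=0):
    """Log-likelihood of the sample at ``params``.

    For DZIOPC the trivariate probabilities are simulated by GHK
    (``method='ghk'``, the default) or computed by deterministic
    quadrature (``method='quadrature'``).
    """
    params.validate()
    _check_dims(params, obs)
    cp = category_probs(params, obs,
                        method=("ghk" if method in ("auto", "ghk") else method),
                        n_draws=n_draws, seed=seed)
    p_obs = cp.probs[np.arange(obs.n), obs.y]
    return float(np.log(np.maximum(p_obs, PROB_FLOOR)).sum())


def _naive_op_start(obs: ObservationSet):
    """Empirical-frequency ordered-probit start: slopes 0, cutpoints from
    the observed cumulative distribution."""
    J = obs.J
    counts = np.bincount(obs.y, minlength=J + 1).astype(float)
    freq = np.clip(counts / counts.sum(), 1e-4, 1.0)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1.0 - 1e-4)
    q = ndtri(cum)
    beta_y = np.zeros(obs.Xy.shape[1])
    if "const" in obs.names_y:
        beta_y[obs.names_y.index("const")] = -q[0]
    mu = q[1:] - q[0]
    mu = np.maximum.accumulate(mu)
    mu += 1e-3 * np.arange(len(mu))  # guard strict ordering
    return beta_y, mu


def _probit_participation(obs: ObservationSet):
    import statsmodels.api as sm

    target = (obs.y > 0).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Probit(target, obs.Xr).fit(disp=0, maxiter=100)
        if np.all(np.isfinite(res.params)):
            return np.asarray(res.params)
        raise ValueError("non-finite probit estimates")
    except Exception:
        warnings.warn("participation probit failed; using zero start",
                      UserWarning, stacklevel=2)
        beta = np.zeros(obs.Xr.shape[1])
        if "const" in obs.names_r:
            share = np.clip((obs.y > 0).mean(), 1e-4, 1 - 1e-4)
            beta[obs.names_r.index("const")] = ndtri(share)
        return beta


def starting_values(obs: ObservationSet, variant: str) -> ParameterSet:
    """Staged warm start.

    (i) probit of 1{y>0} on Xr for the participation coefficients;
    (ii) a fast ordered-probit ML fit for the consumption coefficients
    and thresholds; (iii) misreporting slopes 0 with intercept 1 (a high
    prior truthful-reporting probability); correlations start at 0.
    """
    obs.validate()
    beta_y0, mu0 = _naive_op_start(obs)
    if variant in ("OP", "GOP"):
        gamma = (np.zeros((obs.J - 1, obs.Z_thresh.shape[1]))
                 if variant == "GOP" and obs.Z_thresh.shape[1] else None)
        return ParameterSet(beta_r=np.empty(0), beta_m=np.empty(0),
                            beta_y=beta_y0, mu=mu0, variant=variant,
                            gamma=gamma)
    # stage (ii): ordered-probit ML refinement of (beta_y, mu)
    op_fit = fit(obs, "OP", max_iter=150, compute_cov=False)
    beta_y, mu = op_fit.params.beta_y, op_fit.params.mu
    beta_r = _probit_participation(obs)
    beta_m = np.zeros(obs.Xm.shape[1])
    if _uses_misreporting(variant) and "const" in obs.names_m:
        beta_m[obs.names_m.index("const")] = 1.0
    return ParameterSet(beta_r=beta_r, beta_m=beta_m, beta_y=beta_y, mu=mu,
                        variant=variant)


def _maximize(evaluator, theta0, tol, max_iter, hess_inv0=None):
    n = evaluator.obs.n
    best = {"f": np.inf, "theta": np.asarray(theta0, dtype=float)}

    def f(theta):
        val = -evaluator.loglik(theta) / n
        if val < best["f"]:
            best["f"] = val
            best["theta"] = np.array(theta)
        return val

    def g(theta):
        return _fd_gradient(f, theta)

    opts = {"gtol": tol, "maxiter": max_iter}
    if hess_inv0 is not None:
        opts["hess_inv0"] = hess_inv0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(f, theta0, jac=g, method="BFGS",
                                options=opts)
    theta_hat = best["theta"] if best["f"] < res.fun - 1e-10 else res.x
    grad = _fd_gradient(f, theta_hat)
    return theta_hat, -f(theta_hat) * n, float(np.abs(grad).max()), int(res.nit)


def fit(obs: ObservationSet, variant: str, *, start: ParameterSet | None = None,
        tol: float = 1e-4, max_iter: int = 300, n_draws: int = 500,
        seed: int = 0, presolve_draws: int = 100, compute_cov: bool = True,
        fix_rho: bool = False) -> FitResult:
    """Quasi-Newton ML fit of ``variant`` on ``obs``.

    Deterministic given the options; ``tol`` applies to the sup-norm of
    the per-observation average score.  DZIOPC is fitted by simulated ML
    at ``n_draws`` GHK draws, preceded by a cheap pre-solve (``presolve_draws``)
    and, before that, a DZIOP fit supplying the warm start; its covariance
    matrices are evaluated on the deterministic quadrature likelihood to
    avoid differencing simulation noise.
    """
    obs.validate()
    if _uses_misreporting(variant) and obs.Xm.shape[1] == 0:
        raise ValueError(f"variant {variant} requires misreporting covariates")
    transform = transform_for(obs, variant, fix_rho=fix_rho)

    if start is not None:
        start.validate()
        theta0 = transform.pack(start)
    elif variant == "DZIOPC":
        warm = fit(obs, "DZIOP", tol=tol, max_iter=max_iter,
                   compute_cov=False)
        theta0 = transform.pack(
            ParameterSet(beta_r=warm.params.beta_r, beta_m=warm.params.beta_m,
                         beta_y=warm.params.beta_y, mu=warm.params.mu,
                         variant="DZIOPC"))
    elif variant == "ZIOPC":
        warm = fit(obs, "ZIOP", tol=tol, max_iter=max_iter, compute_cov=False)
        theta0 = transform.pack(
            ParameterSet(beta_r=warm.params.beta_r, beta_m=np.empty(0),
                         beta_y=warm.params.beta_y, mu=warm.params.mu,
                         variant="ZIOPC"))
    else:
        theta0 = transform.pack(starting_values(obs, variant))

    use_ghk = variant == "DZIOPC"
    hess_inv0 = None
    if use_ghk and presolve_draws and presolve_draws < n_draws:
        pre = GhkEvaluator(obs, transform, n_draws=presolve_draws, seed=seed)
        theta0, _, _, _ = _maximize(pre, theta0, tol, max_iter)
        # curvature from the deterministic quadrature likelihood seeds the
        # final stage's BFGS, which then needs only a handful of steps
        quad = AnalyticEvaluator(obs, transform)
        H = _fd_hessian(lambda t: -quad.loglik(t) / obs.n, theta0)
        if np.all(np.isfinite(H)):
            evals, evecs = np.linalg.eigh(0.5 * (H + H.T))
            evals = np.maximum(evals, 1e-6 * max(float(evals.max()), 1e-6))
            Hi = (evecs / evals) @ evecs.T
            Hi = 0.5 * (Hi + Hi.T)
            try:
                np.linalg.cholesky(Hi)
                hess_inv0 = Hi
            except np.linalg.LinAlgError:
                hess_inv0 = None
    evaluator = (GhkEvaluator(obs, transform, n_draws=n_draws, seed=seed)
                 if use_ghk else AnalyticEvaluator(obs, transform))
    ll0 = evaluator.loglik(theta0)
    theta_hat, ll_hat, gnorm, nit = _maximize(evaluator, theta0, tol,
                                              max_iter, hess_inv0=hess_inv0)
    if ll_hat < ll0:  # safeguard: never report a worse point than the start
        theta_hat, ll_hat = theta0, ll0
        gnorm = float(np.abs(_fd_gradient(
            lambda t: -evaluator.loglik(t) / obs.n, theta_hat)).max())
    converged = bool(gnorm <= tol)
    params_hat = transform.unpack(theta_hat)
    params_hat.validate()

    near = []
    if transform.n_rho:
        rho_names = (["rho_ry"] if transform.n_rho == 1
                     else ["rho_rm", "rho_ry", "rho_my"])
        rho_vals = ([params_hat.rho_ry] if transform.n_rho == 1
                    else list(params_hat.rho))
        near = [nm for nm, v in zip(rho_names, rho_vals)
                if abs(v) >= RHO_EDGE]
        if near:
            warnings.warn(
                f"correlation(s) {near} close to the |rho| <= {RHO_BOUND} "
                "bound; these are weakly identified", UserWarning,
                stacklevel=2)

    result = FitResult(
        params=params_hat, loglik=ll_hat, param_names=transform.names(obs),
        estimates=transform.reported(theta_hat), cov_robust=None,
        cov_hessian=None, gradient_norm=gnorm, n_iterations=nit,
        converged=converged, n_obs=obs.n, variant=variant,
        seed=seed if use_ghk else None, n_draws=n_draws if use_ghk else None,
        rho_near_boundary=near, theta=theta_hat, transform=transform)
    if compute_cov:
        try:
            _attach_covariances(result, obs)
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"covariance unavailable: {exc}", UserWarning,
                          stacklevel=2)
    return result


def _cov_evaluator(fitres: FitResult, obs: ObservationSet):
    # quadrature likelihood for DZIOPC: deterministic derivatives; 16
    # nodes give ~1e-8 probabilities, ample for finite-difference Hessians
    return AnalyticEvaluator(obs, fitres.transform, n_nodes=16)


def _attach_covariances(fitres: FitResult, obs: ObservationSet):
    ev = _cov_evaluator(fitres, obs)
    theta = fitres.theta
    H = _fd_hessian(lambda t: ev.loglik(t) / obs.n, theta) * obs.n
    G = _fd_scores(ev.loglik_vec, theta)
    negH = -H
    cond = np.linalg.cond(negH)
    if not np.isfinite(cond) or cond > 1e12:
        curv = np.abs(np.diag(negH))
        bad = [fitres.param_names[i]
               for i in np.where(curv < 1e-8 * max(curv.max(), 1.0))[0]]
        raise np.linalg.LinAlgError(
            f"Hessian is singular (cond={cond:.2e}); "
            f"flat directions involve: {bad or 'mixed directions'}")
    Hinv = np.linalg.inv(negH)
    B = G.T @ G
    cov_u = Hinv @ B @ Hinv
    Jc = fitres.transform.reported_jacobian(theta)
    fitres.cov_unconstrained = 0.5 * (cov_u + cov_u.T)
    fitres.cov_hessian_unconstrained = 0.5 * (Hinv + Hinv.T)
    cov_rep = Jc @ fitres.cov_unconstrained @ Jc.T
    covh_rep = Jc @ fitres.cov_hessian_unconstrained @ Jc.T
    fitres.cov_robust = 0.5 * (cov_rep + cov_rep.T)
    fitres.cov_hessian = 0.5 * (covh_rep + covh_rep.T)


def sandwich_cov(fitres: FitResult, obs: ObservationSet) -> np.ndarray:
    """Robust sandwich covariance H^-1 (sum g_i g_i') H^-1 at the estimates,
    in the reported parameterization."""
    if not fitres.converged:
        warnings.warn("sandwich covariance at a non-converged fit",
                      UserWarning, stacklevel=2)
    _attach_covariances(fitres, obs)
    return fitres.cov_robust


def lr_independence_test(fit_corr: FitResult, fit_indep: FitResult) -> LRTestResult:
    """LR test of Omega3 = I3: the correlated model against its nested
    independent-errors version (statistic clipped at 0, chi-square tail)."""
    pairs = {("DZIOPC", "DZIOP"): 3, ("ZIOPC", "ZIOP"): 1}
    key = (fit_corr.variant, fit_indep.variant)
    if key not in pairs:
        raise ValueError(
            f"independence test requires a (correlated, independent) nested "
            f"pair, got {key}")
    if fit_corr.n_obs != fit_indep.n_obs:
        raise ValueError("fits are not on the same observations")
    if len(fit_corr.estimates) - pairs[key] != len(fit_indep.estimates):
        raise ValueError("fits do not share the same equation specification")
    stat = max(0.0, 2.0 * (fit_corr.loglik - fit_indep.loglik))
    df = pairs[key]
    return LRTestResult(statistic=stat, df=df,
                        p_value=float(stats.chi2.sf(stat, df)))
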