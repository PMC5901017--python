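"""Domain types and category probabilities for the zero-inflated OP family.

The observed ordinal outcome y in {0, ..., J} is generated by up to three
latent Gaussian equations:

* participation:      r* = xr'br + er,   r = 1{r* > 0}
* truthful reporting: m* = xm'bm + em,   m = 1{m* > 0}  (m = 0: misreporter)
* consumption:        yt* = xy'by + ey,  yt = j iff mu_{j-1} < yt* <= mu_j

with the observability rule y = r * m * yt, so an observed zero can come
from a nonparticipant, a misreporting participant, or a truthful
participant with zero consumption ("double inflation" of the zero cell).
Model variants:

==========  ============================================================
OP          plain ordered probit (no hurdles)
GOP         ordered probit with covariate-dependent thresholds
ZIOP/ZIOPC  participation hurdle only (C: correlated errors)
DZIOP       participation + misreporting hurdles, independent errors
DZIOPC      as DZIOP with trivariate-normal errors (correlation Omega3)
==========  ============================================================

The boundary normalisations are mu_0 = 0 and mu_J = +inf, and all error
variances are 1 (probit scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .mvnorm import bvnu, halton_uniforms, tri_lower2_band
from ._ghk import ghk_stage1, ghk_stage2, ghk_stage3

__all__ = [
    "VARIANTS",
    "EquationSpec",
    "ParameterSet",
    "ObservationSet",
    "CategoryProbabilities",
    "build_design",
    "category_probs",
    "zero_components",
]

VARIANTS = ("OP", "GOP", "ZIOP", "ZIOPC", "DZIOP", "DZIOPC")

#: probability floor applied before taking logs
PROB_FLOOR = 1e-300


def _uses_participation(variant):
    return variant in ("ZIOP", "ZIOPC", "DZIOP", "DZIOPC")


def _uses_misreporting(variant):
    return variant in ("DZIOP", "DZIOPC")


def _is_correlated(variant):
    return variant in ("ZIOPC", "DZIOPC")


@dataclass
class EquationSpec:
    """Names of the data columns entering each latent equation.

    ``threshold_columns`` is only used by the GOP variant, where the
    thresholds are functions of those covariates.  Intercepts are added as
    a leading column of ones when the corresponding flag is set.
    """

    outcome_column: str
    xr_columns: list = field(default_factory=list)
    xm_columns: list = field(default_factory=list)
    xy_columns: list = field(default_factory=list)
    threshold_columns: list = field(default_factory=list)
    intercept_r: bool = True
    intercept_m: bool = True
    intercept_y: bool = True

    def validate(self, data: pd.DataFrame, variant: str | None = None):
        all_cols = ([self.outcome_column] + list(self.xr_columns)
                    + list(self.xm_columns) + list(self.xy_columns)
                    + list(self.threshold_columns))
        missing = [c for c in all_cols if c not in data.columns]
        if missing:
            raise KeyError(f"columns not found in data table: {missing}")
        if variant in ("DZIOP", "DZIOPC"):
            xr, xm = set(self.xr_columns), set(self.xm_columns)
            if not (xr - xm) or not (xm - xr):
                warnings.warn(
                    "no exclusion restrictions between the participation and "
                    "misreporting equations; identification relies on "
                    "functional form only", UserWarning, stacklevel=2)


@dataclass
class ParameterSet:
    """Coefficients, thresholds and error correlations of one model variant.

    ``mu`` holds the J-1 free thresholds (0 < mu_1 < ... < mu_{J-1}); for
    GOP these are the baseline thresholds at threshold-covariates zero and
    ``gamma`` (shape (J-1, n_threshold_covariates)) shifts them per row
    through a cumulative-exponential map that preserves their ordering.
    """

    beta_r: np.ndarray
    beta_m: np.ndarray
    beta_y: np.ndarray
    mu: np.ndarray
    rho_rm: float = 0.0
    rho_ry: float = 0.0
    rho_my: float = 0.0
    variant: str = "DZIOP"
    gamma: np.ndarray | None = None

    def __post_init__(self):
        self.beta_r = np.atleast_1d(np.asarray(self.beta_r, dtype=float))
        self.beta_m = np.atleast_1d(np.asarray(self.beta_m, dtype=float))
        self.beta_y = np.atleast_1d(np.asarray(self.beta_y, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)

    @property
    def rho(self):
        return np.array([self.rho_rm, self.rho_ry, self.rho_my])

    def omega3(self):
        """The 3x3 error correlation matrix (r, m, y ordering)."""
        r = self.rho
        return np.array([[1.0, r[0], r[1]],
                         [r[0], 1.0, r[2]],
                         [r[1], r[2], 1.0]])

    def validate(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.mu.size:
            if self.mu[0] <= 0.0 or np.any(np.diff(self.mu) <= 0.0):
                raise ValueError(
                    "thresholds must satisfy 0 < mu_1 < ... < mu_{J-1}, "
                    f"got {self.mu}")
        if not _is_correlated(self.variant):
            if np.any(self.rho != 0.0):
                raise ValueError(
                    f"variant {self.variant} requires zero correlations")
        else:
            if np.any(np.abs(self.rho) >= 1.0):
                raise ValueError("correlations must lie in (-1, 1)")
            eigs = np.linalg.eigvalsh(self.omega3())
            if eigs.min() <= 0.0:
                raise ValueError(
                    "correlation matrix Omega3 is not positive definite "
                    f"(eigenvalues {np.round(eigs, 6)})")
        if self.variant == "ZIOPC" and self.rho_rm == 0.0 and self.rho_my != 0.0:
            raise ValueError("ZIOPC uses only the participation-consumption "
                             "correlation rho_ry")
        return self


@dataclass
class ObservationSet:
    """Outcome vector and aligned design matrices for one data table."""

    y: np.ndarray
    Xr: np.ndarray
    Xm: np.ndarray
    Xy: np.ndarray
    Z_thresh: np.ndarray
    names_r: list
    names_m: list
    names_y: list
    names_thresh: list
    n: int
    J: int

    def validate(self):
        y = self.y
        if y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if not np.all(y == np.round(y)) or np.any(y < 0):
            raise ValueError("outcome must contain nonnegative integers")
        if self.J < 2:
            raise ValueError("need at least three outcome categories (J >= 2)")
        for name, X in (("Xr", self.Xr), ("Xm", self.Xm), ("Xy", self.Xy),
                        ("Z_thresh", self.Z_thresh)):
            if X.shape[0] != self.n:
                raise ValueError(f"{name} has {X.shape[0]} rows, expected {self.n}")
            if not np.all(np.isfinite(X)):
                raise ValueError(f"{name} contains missing/non-finite values")
        counts = np.bincount(y.astype(int), minlength=self.J + 1)
        empty = np.where(counts == 0)[0]
        if empty.size:
            warnings.warn(
                f"outcome categories {empty.tolist()} have no observations; "
                "estimation may be unstable", UserWarning, stacklevel=2)
        return self


@dataclass
class CategoryProbabilities:
    """Per-row probabilities over the outcome categories 0..J."""

    probs: np.ndarray  # (n, J+1)

    def validate(self, atol=1e-10):
        p = self.probs
        if np.any(p < -atol) or np.any(p > 1.0 + atol):
            raise ValueError("category probabilities outside [0, 1]")
        s = p.sum(axis=1)
        if np.any(np.abs(s - 1.0) > atol):
            raise ValueError(
                f"category probabilities do not sum to 1 (max dev "
                f"{np.abs(s - 1.0).max():.3e})")
        return self


def _design(data, columns, intercept):
    cols = [np.asarray(data[c], dtype=float) for c in columns]
    if intercept:
        cols = [np.ones(len(data))] + cols
    names = (["const"] if intercept else []) + list(columns)
    if not cols:
        return np.empty((len(data), 0)), []
    return np.column_stack(cols), names


def build_design(data: pd.DataFrame, spec: EquationSpec,
                 variant: str | None = None) -> ObservationSet:
    """Build the outcome vector and design matrices from a data table.

    The highest category J is inferred as max(y).  Intercept columns of
    ones are prepended where the spec requests them.
    """
    spec.validate(data, variant)
    y_raw = np.asarray(data[spec.outcome_column], dtype=float)
    if np.any(~np.isfinite(y_raw)):
        raise ValueError("outcome column contains missing values")
    if np.any(y_raw != np.round(y_raw)):
        raise ValueError("outcome column must be integer-valued")
    if np.any(y_raw < 0):
        raise ValueError("outcome values must be nonnegative")
    y = y_raw.astype(int)
    J = int(y.max())
    Xr, names_r = _design(data, spec.xr_columns, spec.intercept_r)
    Xm, names_m = _design(data, spec.xm_columns, spec.intercept_m)
    Xy, names_y = _design(data, spec.xy_columns, spec.intercept_y)
    Zt, names_t = _design(data, spec.threshold_columns, False)
    obs = ObservationSet(y=y, Xr=Xr, Xm=Xm, Xy=Xy, Z_thresh=Zt,
                         names_r=names_r, names_m=names_m, names_y=names_y,
                         names_thresh=names_t, n=len(y), J=J)
    return obs.validate()


def _check_dims(params: ParameterSet, obs: ObservationSet):
    v = params.variant
    if _uses_participation(v) and params.beta_r.size != obs.Xr.shape[1]:
        raise ValueError(
            f"beta_r has length {params.beta_r.size}, Xr has "
            f"{obs.Xr.shape[1]} columns")
    if _uses_misreporting(v) and params.beta_m.size != obs.Xm.shape[1]:
        raise ValueError(
            f"beta_m has length {params.beta_m.size}, Xm has "
            f"{obs.Xm.shape[1]} columns")
    if params.beta_y.size != obs.Xy.shape[1]:
        raise ValueError(
            f"beta_y has length {params.beta_y.size}, Xy has "
            f"{obs.Xy.shape[1]} columns")
    if params.mu.size != obs.J - 1:
        raise ValueError(
            f"mu has length {params.mu.size}, expected J-1 = {obs.J - 1}")
    if v == "GOP" and params.gamma is not None and obs.Z_thresh.shape[1]:
        if params.gamma.shape != (obs.J - 1, obs.Z_thresh.shape[1]):
            raise ValueError("gamma must have shape (J-1, n_threshold_cols)")


def _row_thresholds(params: ParameterSet, obs: ObservationSet):
    """Per-row thresholds (n, J-1); constant rows except for GOP.

    GOP uses the cumulative-exponential map mu_j(z) = sum_{k<=j}
    exp(c_k + z'gamma_k), with c_k = log(mu_k - mu_{k-1}), which keeps the
    thresholds strictly increasing for every z and any coefficients.
    """
    J = obs.J
    base = params.mu
    if params.variant != "GOP" or params.gamma is None or not obs.Z_thresh.shape[1]:
        return np.broadcast_to(base, (obs.n, J - 1))
    steps = np.concatenate([[base[0]], np.diff(base)])
    c = np.log(steps)  # (J-1,)
    shift = obs.Z_thresh @ params.gamma.T  # (n, J-1)
    return np.cumsum(np.exp(c[None, :] + shift), axis=1)


def _op_band_probs(ay, mu_rows, J):
    """Ordered-probit band probabilities P(mu_{j-1} < yt* <= mu_j): (n, J+1)."""
    n = ay.shape[0]
    cuts = np.column_stack([np.zeros(n), mu_rows])  # mu_0 = 0 prepended
    cdf = ndtr(cuts - ay[:, None])  # (n, J)
    out = np.empty((n, J + 1))
    out[:, 0] = cdf[:, 0]
    out[:, 1:J] = np.diff(cdf, axis=1)
    out[:, J] = 1.0 - cdf[:, -1]
    return out


def _indices(params, obs):
    ar = obs.Xr @ params.beta_r if params.beta_r.size else np.zeros(obs.n)
    am = obs.Xm @ params.beta_m if params.beta_m.size else np.zeros(obs.n)
    ay = obs.Xy @ params.beta_y
    return ar, am, ay


def _band_edges(mu_rows, ay, J):
    """Lower/upper integration limits for ey in each category band."""
    n = ay.shape[0]
    cuts = np.column_stack([np.zeros(n), mu_rows])  # [0, mu_1, .., mu_{J-1}]
    lo = np.empty((n, J + 1))
    hi = np.empty((n, J + 1))
    lo[:, 0] = -np.inf
    hi[:, 0] = -ay
    for j in range(1, J):
        lo[:, j] = cuts[:, j - 1] - ay
        hi[:, j] = cuts[:, j] - ay
    lo[:, J] = cuts[:, J - 1] - ay
    hi[:, J] = np.inf
    return lo, hi


def _dziopc_probs_quadrature(params, obs, n_nodes):
    ar, am, ay = _indices(params, obs)
    mu_rows = _row_thresholds(params, obs)
    J = obs.J
    lo, hi = _band_edges(mu_rows, ay, J)
    out = np.empty((obs.n, J + 1))
    for j in range(1, J + 1):
        out[:, j] = tri_lower2_band(-ar, -am, lo[:, j], hi[:, j],
                                    params.rho_rm, params.rho_ry,
                                    params.rho_my, n_nodes=n_nodes)
    comp = _dziopc_zero_components(params, ar, am, ay, n_nodes)
    out[:, 0] = comp.sum(axis=1)
    return out


def _dziopc_probs_ghk(params, obs, n_draws, seed):
    ar, am, ay = _indices(params, obs)
    mu_rows = _row_thresholds(params, obs)
    J = obs.J
    lo, hi = _band_edges(mu_rows, ay, J)
    chol = np.linalg.cholesky(params.omega3())
    u1, u2 = halton_uniforms(n_draws, seed)
    p1, z1 = ghk_stage1(-ar, np.full(obs.n, np.inf), u1)
    p2, z2 = ghk_stage2(-am, np.full(obs.n, np.inf), z1, u2,
                        chol[1, 0], chol[1, 1])
    out = np.empty((obs.n, J + 1))
    for j in range(1, J + 1):
        s3 = ghk_stage3(np.ascontiguousarray(lo[:, j]),
                        np.ascontiguousarray(hi[:, j]), z1, z2, p2,
                        chol[2, 0], chol[2, 1], chol[2, 2])
        out[:, j] = p1 * s3
    out[:, 0] = 1.0 - out[:, 1:].sum(axis=1)
    return out


def _dziopc_zero_components(params, ar, am, ay, n_nodes):
    """The three zero sources under correlated errors."""
    comp = np.empty((ar.shape[0], 3))
    comp[:, 0] = ndtr(-ar)
    # P(r=1, m=0) = P(er > -ar) - P(er > -ar, em > -am)
    comp[:, 1] = np.clip(ndtr(ar) - bvnu(-ar, -am, params.rho_rm), 0.0, 1.0)
    comp[:, 2] = tri_lower2_band(-ar, -am, np.full_like(ar, -np.inf), -ay,
                                 params.rho_rm, params.rho_ry, params.rho_my,
                                 n_nodes=n_nodes)
    return comp


def category_probs(params: ParameterSet, obs: ObservationSet,
                   method: str = "auto", n_draws: int = 500, seed: int = 0,
                   n_nodes: int = 16) -> CategoryProbabilities:
    """Per-row probabilities of each outcome category under the variant.

    For DZIOPC the trivariate probabilities are computed by deterministic
    quadrature (``method='quadrature'``, the default) or by the GHK
    simulator (``method='ghk'``, controlled by ``n_draws``/``seed``).
    """
    params.validate()
    _check_dims(params, obs)
    v = params.variant
    J = obs.J
    ar, am, ay = _indices(params, obs)
    mu_rows = _row_thresholds(params, obs)

    if v in ("OP", "GOP"):
        out = _op_band_probs(ay, mu_rows, J)
    elif v == "ZIOP":
        op = _op_band_probs(ay, mu_rows, J)
        pr = ndtr(ar)
        out = pr[:, None] * op
        out[:, 0] = ndtr(-ar) + pr * op[:, 0]
    elif v == "ZIOPC":
        lo, hi = _band_edges(mu_rows, ay, J)
        out = np.empty((obs.n, J + 1))
        for j in range(1, J + 1):
            out[:, j] = np.clip(
                bvnu(-ar, lo[:, j], params.rho_ry)
                - bvnu(-ar, hi[:, j], params.rho_ry), 0.0, 1.0)
        out[:, 0] = 1.0 - out[:, 1:].sum(axis=1)
    elif v == "DZIOP":
        op = _op_band_probs(ay, mu_rows, J)
        pr, pm = ndtr(ar), ndtr(am)
        out = (pr * pm)[:, None] * op
        out[:, 0] = ndtr(-ar) + pr * ndtr(-am) + pr * pm * op[:, 0]
    elif v == "DZIOPC":
        if method == "ghk":
            out = _dziopc_probs_ghk(params, obs, n_draws, seed)
        else:
            out = _dziopc_probs_quadrature(params, obs, n_nodes)
    else:  # pragma: no cover
        raise ValueError(f"unknown variant {v!r}")

    tol = 1e-6 if (v == "DZIOPC" and method == "ghk") else 1e-10
    return CategoryProbabilities(np.clip(out, 0.0, 1.0)).validate(atol=tol)


def zero_components(params: ParameterSet, obs: ObservationSet,
                    n_nodes: int = 16) -> np.ndarray:
    """Per-row decomposition of Pr(y=0) into its three sources.

    Columns: nonparticipation Pr(r=0); participant misreporting
    Pr(r=1, m=0); truthful zero consumption Pr(r=1, m=1, yt=0).  The
    three sum to Pr(y=0).  Only defined for DZIOP/DZIOPC.
    """
    if params.variant not in ("DZIOP", "DZIOPC"):
        raise ValueError(
            f"variant {params.variant} has no misreporting equation; zero "
            "decomposition requires DZIOP or DZIOPC")
    params.validate()
    _check_dims(params, obs)
    ar, am, ay = _indices(params, obs)
    if params.variant == "DZIOP":
        comp = np.empty((obs.n, 3))
        pr, pm = ndtr(ar), ndtr(am)
        comp[:, 0] = ndtr(-ar)
        comp[:, 1] = pr * ndtr(-am)
        comp[:, 2] = pr * pm * ndtr(-ay)
        return comp
    return _dziopc_zero_components(params, ar, am, ay, n_nodes)
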