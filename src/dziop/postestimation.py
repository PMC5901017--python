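"""Partial effects, zero-probability decompositions, posterior attribution.

Partial effects on the model probabilities are computed numerically:
continuous covariates by central differences, binary covariates by the
discrete 0 -> 1 change (configurable).  A covariate appearing in several
equations receives its total effect through all channels.  For the
double-hurdle variants the effect on Pr(y=0) is decomposed over the three
zero sources — nonparticipation, participant misreporting, truthful zero
consumption — and the three component effects sum to the overall effect
by construction.

Posterior zero shares answer: *given that a row reported zero, what is the
probability it is a nonparticipant / a misreporter / a truthful
infrequent consumer?*  They are the prior zero components normalised by
their sum, evaluated row by row and averaged over the observed zeros.

Standard errors of all derived quantities use the delta method with
numerical Jacobians over the unconstrained parameter vector, combined
with the robust (sandwich) parameter covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import GRAD_STEP, FitResult
from .model_core import ObservationSet, category_probs, zero_components

__all__ = [
    "PartialEffectTable",
    "PosteriorShares",
    "ZeroDecomposition",
    "partial_effects",
    "posterior_zero_shares",
    "prior_zero_summary",
    "format_zero_table",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass
class PartialEffectTable:
    variant: str
    mode: str
    covariates: list
    quantity_names: list
    effects: np.ndarray           # (n_cov, n_quantities)
    ses: np.ndarray | None        # same shape, delta method
    n_components: int             # leading columns that decompose Pr(y=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.effects, index=self.covariates,
                          columns=self.quantity_names)
        if self.ses is not None:
            for j, q in enumerate(self.quantity_names):
                df[f"se({q})"] = self.ses[:, j]
        return df


@dataclass
class PosteriorShares:
    per_row: np.ndarray           # (n_zero_rows, 3)
    average: np.ndarray           # (3,)
    se: np.ndarray | None
    n_zero: int

    def validate(self):
        if np.any(self.per_row < -1e-12):
            raise ValueError("negative posterior share")
        dev = np.abs(self.per_row.sum(axis=1) - 1.0).max()
        if dev > 1e-10:
            raise ValueError(f"posterior shares do not sum to 1 (dev {dev:.2e})")
        return self


@dataclass
class ZeroDecomposition:
    components: np.ndarray        # (3,) averaged over all rows
    total: float                  # = average Pr(y=0)
    se: np.ndarray | None         # (4,): three components and the total


# ---------------------------------------------------------------------------
# helpers

def _mean_row_obs(obs: ObservationSet) -> ObservationSet:
    """One-row observation set at the arithmetic means of every design
    column (dummies and squared terms included, each treated as its own
    regressor)."""
    return ObservationSet(
        y=np.zeros(1, dtype=int), n=1, J=obs.J,
        Xr=obs.Xr.mean(axis=0, keepdims=True),
        Xm=obs.Xm.mean(axis=0, keepdims=True),
        Xy=obs.Xy.mean(axis=0, keepdims=True),
        Z_thresh=obs.Z_thresh.mean(axis=0, keepdims=True),
        names_r=obs.names_r, names_m=obs.names_m, names_y=obs.names_y,
        names_thresh=obs.names_thresh)


def _clone_with(obs: ObservationSet, **mats) -> ObservationSet:
    return ObservationSet(
        y=obs.y, n=obs.n, J=obs.J,
        Xr=mats.get("Xr", obs.Xr), Xm=mats.get("Xm", obs.Xm),
        Xy=mats.get("Xy", obs.Xy), Z_thresh=mats.get("Z_thresh", obs.Z_thresh),
        names_r=obs.names_r, names_m=obs.names_m, names_y=obs.names_y,
        names_thresh=obs.names_thresh)


def _set_covariate(obs: ObservationSet, name: str, value) -> ObservationSet:
    mats = {}
    for attr, names in (("Xr", obs.names_r), ("Xm", obs.names_m),
                        ("Xy", obs.names_y), ("Z_thresh", obs.names_thresh)):
        if name in names:
            X = getattr(obs, attr).copy()
            X[:, names.index(name)] = value
            mats[attr] = X
    return _clone_with(obs, **mats) if mats else obs


def _covariate_column(obs: ObservationSet, name: str):
    for attr, names in (("Xr", obs.names_r), ("Xm", obs.names_m),
                        ("Xy", obs.names_y), ("Z_thresh", obs.names_thresh)):
        if name in names:
            return getattr(obs, attr)[:, names.index(name)]
    return None


def _quantities(params, obsw: ObservationSet, n_nodes=16):
    """Averaged probability quantities whose covariate responses we report."""
    cp = category_probs(params, obsw, method="quadrature", n_nodes=n_nodes)
    cats = cp.probs.mean(axis=0)
    v = params.variant
    if v in ("DZIOP", "DZIOPC"):
        comps = zero_components(params, obsw, n_nodes=n_nodes).mean(axis=0)
        return np.concatenate([comps, cats])
    if v in ("ZIOP", "ZIOPC"):
        from scipy.special import ndtr
        ar = obsw.Xr @ params.beta_r
        p_nonpart = float(ndtr(-ar).mean())
        return np.concatenate([[p_nonpart, cats[0] - p_nonpart], cats])
    return cats


def _quantity_names(variant, J):
    cats = [f"Pr(y={j})" for j in range(J + 1)]
    if variant in ("DZIOP", "DZIOPC"):
        return (["Pr(r=0)", "Pr(r=1,m=0)", "Pr(r=1,m=1,yt=0)"] + cats, 3)
    if variant in ("ZIOP", "ZIOPC"):
        return (["Pr(r=0)", "Pr(r=1,yt=0)"] + cats, 2)
    return (cats, 0)


def _is_binary(col):
    return col is not None and np.all(np.isin(col, (0.0, 1.0)))


def _theta_jacobian(func, fitres: FitResult, step=GRAD_STEP):
    """FD Jacobian of func(theta) over the unconstrained parameters."""
    theta = fitres.theta
    cols = []
    for k in range(theta.size):
        h = step * (1.0 + abs(theta[k]))
        tp = theta.copy()
        tp[k] += h
        tm = theta.copy()
        tm[k] -= h
        cols.append((func(tp) - func(tm)) / (2.0 * h))
    return np.column_stack(cols)


def _delta_se(func, fitres: FitResult):
    if fitres.cov_unconstrained is None:
        return None
    J = _theta_jacobian(func, fitres)
    var = np.einsum("ij,jk,ik->i", J, fitres.cov_unconstrained, J)
    return np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------------------
# operations

def partial_effects(fitres: FitResult, obs: ObservationSet,
                    mode: str = "at_means", dummy_handling: str = "discrete",
                    covariates=None, compute_se: bool = True,
                    n_nodes: int = 16) -> PartialEffectTable:
    """Numerical partial effects of each covariate on the model
    probabilities, decomposed over the zero sources.

    mode 'at_means' evaluates at the sample means of all design columns;
    'average' averages the per-row responses.  Binary covariates get the
    discrete 0 -> 1 change unless ``dummy_handling='derivative'``.
    A requested covariate absent from every equation has effect 0, SE 0.
    """
    if mode not in ("at_means", "average"):
        raise ValueError(f"unknown mode {mode!r}")
    if dummy_handling not in ("discrete", "derivative"):
        raise ValueError(f"unknown dummy_handling {dummy_handling!r}")
    transform = fitres.transform
    obsw = _mean_row_obs(obs) if mode == "at_means" else obs
    names, n_comp = _quantity_names(fitres.variant, obs.J)
    if covariates is None:
        seen = []
        for group in (obs.names_r, obs.names_m, obs.names_y, obs.names_thresh):
            for c in group:
                if c != "const" and c not in seen:
                    seen.append(c)
        covariates = seen

    def effect_vector(theta):
        params = transform.unpack(theta)
        rows = []
        for name in covariates:
            col = _covariate_column(obs, name)
            if col is None:
                rows.append(np.zeros(len(names)))
                continue
            if _is_binary(col) and dummy_handling == "discrete":
                q1 = _quantities(params, _set_covariate(obsw, name, 1.0), n_nodes)
                q0 = _quantities(params, _set_covariate(obsw, name, 0.0), n_nodes)
                rows.append(q1 - q0)
            else:
                base = _covariate_column(obsw, name)
                h = 1e-6 * max(1.0, float(np.abs(base).max()))
                qp = _quantities(params, _set_covariate(obsw, name, base + h),
                                 n_nodes)
                qm = _quantities(params, _set_covariate(obsw, name, base - h),
                                 n_nodes)
                rows.append((qp - qm) / (2.0 * h))
        return np.concatenate(rows)

    eff = effect_vector(fitres.theta).reshape(len(covariates), len(names))
    ses = None
    if compute_se:
        se_flat = _delta_se(effect_vector, fitres)
        if se_flat is not None:
            ses = se_flat.reshape(len(covariates), len(names))
            for i, name in enumerate(covariates):
                if _covariate_column(obs, name) is None:
                    ses[i, :] = 0.0
    return PartialEffectTable(variant=fitres.variant, mode=mode,
                              covariates=list(covariates),
                              quantity_names=names, effects=eff, ses=ses,
                              n_components=n_comp)


def posterior_zero_shares(fitres: FitResult, obs: ObservationSet,
                          compute_se: bool = True,
                          n_nodes: int = 16) -> PosteriorShares:
    """Posterior probabilities of the three zero sources among the rows
    that reported zero: prior components normalised by their sum."""
    zmask = obs.y == 0
    if not np.any(zmask):
        raise ValueError("no zero observations: posterior shares undefined")
    sub = _clone_with(obs)
    sub = ObservationSet(
        y=obs.y[zmask], n=int(zmask.sum()), J=obs.J,
        Xr=obs.Xr[zmask], Xm=obs.Xm[zmask], Xy=obs.Xy[zmask],
        Z_thresh=(obs.Z_thresh[zmask] if obs.Z_thresh.size else
                  obs.Z_thresh[:0]),
        names_r=obs.names_r, names_m=obs.names_m, names_y=obs.names_y,
        names_thresh=obs.names_thresh)

    def shares_mean(theta):
        params = fitres.transform.unpack(theta)
        comp = zero_components(params, sub, n_nodes=n_nodes)
        denom = np.maximum(comp.sum(axis=1, keepdims=True), 1e-300)
        return (comp / denom).mean(axis=0)

    params = fitres.params
    comp = zero_components(params, sub, n_nodes=n_nodes)
    denom = np.maximum(comp.sum(axis=1, keepdims=True), 1e-300)
    per_row = comp / denom
    se = _delta_se(shares_mean, fitres) if compute_se else None
    return PosteriorShares(per_row=per_row, average=per_row.mean(axis=0),
                           se=se, n_zero=sub.n).validate()


def prior_zero_summary(fitres: FitResult, obs: ObservationSet,
                       compute_se: bool = True,
                       n_nodes: int = 16) -> ZeroDecomposition:
    """Sample-average prior decomposition of Pr(y=0) over the three zero
    sources, across *all* rows; the components sum to the average
    predicted zero probability."""

    def comp_and_total(theta):
        params = fitres.transform.unpack(theta)
        c = zero_components(params, obs, n_nodes=n_nodes).mean(axis=0)
        return np.concatenate([c, [c.sum()]])

    c = zero_components(fitres.params, obs, n_nodes=n_nodes).mean(axis=0)
    se = _delta_se(comp_and_total, fitres) if compute_se else None
    return ZeroDecomposition(components=c, total=float(c.sum()), se=se)


def format_zero_table(prior: ZeroDecomposition,
                      posterior: PosteriorShares) -> str:
    """Two-row summary of the zero decomposition: averaged marginal
    probabilities of the three sources (with total) and the averaged
    posterior shares among observed zeros (summing to 1)."""
    head = (f"{'':28s}{'Non-part.':>12s}{'Misreport':>12s}"
            f"{'Zero-cons.':>12s}{'Full':>10s}")
    lines = [head]
    vals = list(prior.components) + [prior.total]
    lines.append("Marginal probability        "
                 + "".join(f"{v:12.3f}" for v in vals[:3]) + f"{vals[3]:10.3f}")
    if prior.se is not None:
        lines.append("  (se)                      "
                     + "".join(f"{s:12.3f}" for s in prior.se[:3])
                     + f"{prior.se[3]:10.3f}")
    post = list(posterior.average) + [posterior.average.sum()]
    lines.append("Posterior probability       "
                 + "".join(f"{v:12.3f}" for v in post[:3]) + f"{post[3]:10.3f}")
    if posterior.se is not None:
        lines.append("  (se)                      "
                     + "".join(f"{s:12.3f}" for s in posterior.se[:3]))
    return "\n".join(lines)
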