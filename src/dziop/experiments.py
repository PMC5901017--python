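"""Reproducible validation experiments for the model family.

These functions implement the package's standing numerical experiments —
oracle cross-checks of the probability engine, probability-normalization
sweeps, nesting identities, simulated parameter recovery, posterior-share
recovery, the misspecification comparison, and the null distribution of
the error-independence test.  They are used by the test suite and by the
reproduction script; every function is deterministic given its seed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .estimation import fit, lr_independence_test
from .model_core import (ParameterSet, build_design, category_probs)
from .mvnorm import ghk_rect_prob, normal_cdf3
from .postestimation import posterior_zero_shares
from .synthetic_data import (cannabis_preset, condensed_preset,
                             independence_test_preset, simulate_dataset,
                             truth_shares)

__all__ = [
    "ghk_oracle_experiment",
    "normalization_experiment",
    "nesting_experiment",
    "dziop_recovery_experiment",
    "dziopc_recovery_experiment",
    "posterior_recovery_check",
    "misspecification_experiment",
    "lr_null_experiment",
]


def _random_pd_corr(rng, scale=0.85):
    t = rng.uniform(-scale, scale, 3)
    r12, r13 = t[0], t[1]
    r23 = r12 * r13 + t[2] * math.sqrt((1 - r12 ** 2) * (1 - r13 ** 2))
    return np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])


def _mc_rect_prob(upper, corr, n_mc, rng, chunk=1_000_000):
    """Brute-force Monte-Carlo orthant probability with chunked draws."""
    chol = np.linalg.cholesky(corr)
    hits = 0
    left = n_mc
    while left > 0:
        m = min(chunk, left)
        z = rng.standard_normal((m, 3)) @ chol.T
        hits += int(np.all(z <= upper, axis=1).sum())
        left -= m
    return hits / n_mc


def ghk_oracle_experiment(seed=0, n_instances=25, n_mc=10_000_000,
                          n_draws=500, n_ghk_seeds=6):
    """Three-way cross-validation of trivariate rectangle probabilities.

    For random correlation matrices and limits, compares the GHK
    simulator (scrambled Halton), deterministic quadrature and a
    brute-force MC count; reports the worst pairwise discrepancy in units
    of 3 combined standard errors (values < 1 mean every pair agreed).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        corr = _random_pd_corr(rng)
        a = rng.normal(0.0, 1.5, 3)
        mc = _mc_rect_prob(a, corr, n_mc, rng)
        se_mc = math.sqrt(max(mc * (1 - mc), 1e-12) / n_mc)
        ghk_reps = [ghk_rect_prob(a, corr, n_draws=n_draws, seed=int(s))
                    for s in rng.integers(0, 2 ** 31 - 1, n_ghk_seeds)]
        ghk = float(np.mean(ghk_reps))
        se_ghk = float(np.std(ghk_reps, ddof=1)) + 2e-6
        quad = normal_cdf3(a, corr, method="quadrature")
        pairs = [(ghk, mc, math.hypot(se_ghk, se_mc)),
                 (quad, mc, se_mc),
                 (ghk, quad, se_ghk)]
        for x, y, se in pairs:
            worst = max(worst, abs(x - y) / (3.0 * se))
    return {"worst_pairwise_z3": worst, "n_instances": n_instances}


def _random_obs(rng, n_rows=20):
    import pandas as pd

    df = pd.DataFrame({"y": np.tile(np.arange(4), n_rows // 4 + 1)[:n_rows],
                       "x": rng.normal(0, 1, n_rows),
                       "w": rng.normal(0, 1, n_rows)})
    from .model_core import EquationSpec

    spec = EquationSpec("y", ["x"], ["w"], ["x", "w"],
                        threshold_columns=["w"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_design(df, spec)


def normalization_experiment(seed=0, n_sets=1000, n_ghk_subset=100):
    """Row-normalization sweep over random parameters and covariates.

    Draws ``n_sets`` random parameter/covariate configurations per model
    variant and records the largest deviation of any row sum of category
    probabilities from 1 (analytic/quadrature paths), plus the deviation
    on the simulated GHK path for a subset.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_ghk = 0.0
    variants = ("OP", "GOP", "ZIOP", "ZIOPC", "DZIOP", "DZIOPC")
    for i in range(n_sets):
        obs = _random_obs(rng)
        v = variants[i % len(variants)]
        corr = _random_pd_corr(rng, scale=0.8)
        kw = {}
        if v == "ZIOPC":
            kw = dict(rho_ry=corr[0, 2])
        elif v == "DZIOPC":
            kw = dict(rho_rm=corr[0, 1], rho_ry=corr[0, 2],
                      rho_my=corr[1, 2])
        p = ParameterSet(
            beta_r=rng.normal(0, 1, 2), beta_m=rng.normal(0, 1, 2),
            beta_y=rng.normal(0, 1, 3),
            mu=np.cumsum(rng.uniform(0.2, 1.0, 2)),
            gamma=(rng.normal(0, 1, (2, 1)) if v == "GOP" else None),
            variant=v, **kw)
        probs = category_probs(p, obs).probs
        worst = max(worst, float(np.abs(probs.sum(axis=1) - 1.0).max()))
        if v == "DZIOPC" and i < 6 * n_ghk_subset:
            pg = category_probs(p, obs, method="ghk", n_draws=200,
                                seed=int(rng.integers(2 ** 31))).probs
            worst_ghk = max(worst_ghk,
                            float(np.abs(pg.sum(axis=1) - 1.0).max()))
    return {"max_rowsum_dev": worst, "max_rowsum_dev_ghk": worst_ghk,
            "n_sets": n_sets}


def nesting_experiment(seed=0, n=2000):
    """Nesting identities on one simulated sample.

    (i) a DZIOPC fit with the correlations frozen at zero must reproduce
    the DZIOP fit's log-likelihood; (ii) DZIOP probabilities with
    degenerate hurdles must reproduce plain ordered-probit probabilities.
    """
    cfg = condensed_preset(n=n, seed=seed, correlated=False)
    table, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = build_design(table, cfg.spec, "DZIOP")
        res_i = fit(obs, "DZIOP", compute_cov=False)
        res_c = fit(obs, "DZIOPC", fix_rho=True, compute_cov=False,
                    n_draws=500, presolve_draws=0)
    rel = abs(res_c.loglik - res_i.loglik) / abs(res_i.loglik)

    p_op = ParameterSet(beta_r=np.empty(0), beta_m=np.empty(0),
                        beta_y=res_i.params.beta_y, mu=res_i.params.mu,
                        variant="OP")
    p_deg = ParameterSet(
        beta_r=np.concatenate([[20.0], np.zeros(obs.Xr.shape[1] - 1)]),
        beta_m=np.concatenate([[20.0], np.zeros(obs.Xm.shape[1] - 1)]),
        beta_y=res_i.params.beta_y, mu=res_i.params.mu, variant="DZIOP")
    dev = float(np.abs(category_probs(p_deg, obs).probs
                       - category_probs(p_op, obs).probs).max())
    return {"loglik_rel_diff": rel, "degenerate_hurdle_dev": dev, "n": n}


def dziop_recovery_experiment(seed=0, n=20_000, n_reps=10):
    """Single-replicate parameter recovery for the uncorrelated model.

    Fits the condensed design at the preset truth; the recovery metric is
    the largest |estimate - truth| over the simulation-based standard
    error (standard deviation of the estimator over ``n_reps`` further
    independent replicates).  Returns the artifacts needed for the
    posterior-share check as well.
    """
    cfg = condensed_preset(n=n, seed=seed, correlated=False)
    table, latents = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = build_design(table, cfg.spec, "DZIOP")
        res = fit(obs, "DZIOP", seed=seed)
    truth = np.concatenate([cfg.params.beta_r, cfg.params.beta_m,
                            cfg.params.beta_y, cfg.params.mu])
    reps = []
    for r in range(n_reps):
        cfg_r = condensed_preset(n=n, seed=seed + 1000 + r, correlated=False)
        table_r, _ = simulate_dataset(cfg_r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs_r = build_design(table_r, cfg_r.spec, "DZIOP")
            reps.append(fit(obs_r, "DZIOP", compute_cov=False).estimates)
    sim_se = np.std(np.array(reps), axis=0, ddof=1)
    z = np.abs(res.estimates - truth) / np.maximum(sim_se, 1e-12)
    return {"max_z": float(z.max()), "z": z, "names": res.param_names,
            "fit": res, "obs": obs, "latents": latents, "config": cfg,
            "n": n}


def dziopc_recovery_experiment(seed=0, n=20_000, n_draws=500,
                               presolve_draws=64):
    """Parameter recovery for the correlated model by simulated ML.

    Single replicate at ``n_draws`` GHK draws; deviations from truth are
    scaled by the robust (sandwich) standard errors of the fit.
    """
    cfg = condensed_preset(n=n, seed=seed, correlated=True)
    table, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = build_design(table, cfg.spec, "DZIOPC")
        res = fit(obs, "DZIOPC", seed=seed, n_draws=n_draws,
                  presolve_draws=presolve_draws)
    truth = np.concatenate([cfg.params.beta_r, cfg.params.beta_m,
                            cfg.params.beta_y, cfg.params.mu,
                            cfg.params.rho])
    se = res.se_robust
    z = np.abs(res.estimates - truth) / np.maximum(se, 1e-12)
    return {"max_z": float(z.max()), "z": z, "names": res.param_names,
            "fit": res, "obs": obs, "config": cfg, "n": n}


def posterior_recovery_check(recovery):
    """Averaged posterior zero shares vs realized latent zero types.

    Two comparisons on the artifacts of ``dziop_recovery_experiment``:
    the posterior attribution evaluated at the *generating* parameters
    against the realized fractions (binomial standard errors — a pure
    check of the attribution formulas), and the attribution at the
    *fitted* parameters against the same fractions (binomial combined
    with the delta-method uncertainty of the estimated shares, since
    parameter noise enters at the same order).
    """
    from .model_core import zero_components

    res, obs, latents, cfg = (recovery["fit"], recovery["obs"],
                              recovery["latents"], recovery["config"])
    realized = truth_shares(latents)
    zmask = obs.y == 0
    n0 = int(zmask.sum())
    se_binom = np.sqrt(np.maximum(realized * (1 - realized), 1e-12) / n0)

    comp_true = zero_components(cfg.params, obs)[zmask]
    shares_true = (comp_true / comp_true.sum(axis=1, keepdims=True)).mean(0)
    z_true = np.abs(shares_true - realized) / se_binom

    shares_fit = posterior_zero_shares(res, obs, compute_se=True)
    se_fit = np.sqrt(se_binom ** 2 + shares_fit.se ** 2)
    z_fit = np.abs(shares_fit.average - realized) / se_fit
    return {"max_z": float(z_true.max()),
            "max_z_fitted": float(z_fit.max()),
            "posterior_true": shares_true,
            "posterior_fitted": shares_fit.average,
            "realized": realized, "n_zero": n0}


def misspecification_experiment(seed=0, n=20_000):
    """Participation-prevalence bias of models that ignore misreporting.

    Simulates the condensed survey design (just under a third of
    participants misreport), then compares each model's implied
    participation prevalence with the realized share of latent
    participants.  OP has no participation equation; its implied
    prevalence is the predicted probability of a positive response.
    """
    cfg = condensed_preset(n=n, seed=seed, correlated=False)
    table, latents = simulate_dataset(cfg)
    true_prev = float(latents["r"].mean())
    out = {"true_participation": true_prev, "n": n}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for variant in ("OP", "ZIOP", "DZIOP"):
            obs = build_design(table, cfg.spec, variant)
            res = fit(obs, variant, compute_cov=False)
            if variant == "OP":
                prev = 1.0 - float(
                    category_probs(res.params, obs).probs[:, 0].mean())
            else:
                prev = float(ndtr(obs.Xr @ res.params.beta_r).mean())
            out[variant] = {"prevalence": prev, "bias": prev - true_prev}
    return out


def lr_null_experiment(seed=0, n_reps=100, n=2000, n_draws=32,
                       level=0.05, tol=3e-4):
    """Empirical size of the error-independence LR test under the null.

    Simulates ``n_reps`` data sets with independent errors, fits the
    independent and correlated models on each, and reports the rejection
    rate at the nominal ``level``.  Economical settings keep the
    replication loop affordable: the null fit starts at the generating
    parameters, the correlated fit warm-starts from the null fit, and the
    GHK simulator runs at ``n_draws`` draws (exact at zero correlation,
    where it matters for the statistic's null behaviour).
    """
    crit = stats.chi2.ppf(1.0 - level, 3)
    rejections = 0
    stats_list = []
    for r in range(n_reps):
        cfg = independence_test_preset(n=n, seed=seed + 17 * r)
        table, _ = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs = build_design(table, cfg.spec, "DZIOP")
            res0 = fit(obs, "DZIOP", start=cfg.params, tol=tol,
                       compute_cov=False)
            start = ParameterSet(
                beta_r=res0.params.beta_r, beta_m=res0.params.beta_m,
                beta_y=res0.params.beta_y, mu=res0.params.mu,
                variant="DZIOPC")
            res1 = fit(obs, "DZIOPC", start=start, n_draws=n_draws,
                       presolve_draws=0, tol=tol, compute_cov=False)
        test = lr_independence_test(res1, res0)
        stats_list.append(test.statistic)
        rejections += int(test.statistic > crit)
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps,
            "statistics": np.array(stats_list), "n": n}
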