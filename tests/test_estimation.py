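"""Likelihood evaluation, warm starts, fitting, inference."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from dziop import (EquationSpec, ParameterSet, build_design,
                   fit, loglik, lr_independence_test, starting_values)
from dziop.estimation import FitResult, transform_for
from dziop.synthetic_data import condensed_preset, simulate_dataset


class TestLoglik:
    def test_single_row_hand_value(self, centered_params):
        from dziop import ObservationSet
        X = np.array([[1.0, 0.0]])
        obs = ObservationSet(y=np.array([0]), Xr=X, Xm=X, Xy=X,
                             Z_thresh=np.empty((1, 0)),
                             names_r=["const", "x"], names_m=["const", "x"],
                             names_y=["const", "x"], names_thresh=[],
                             n=1, J=3)
        ll = loglik(centered_params, obs)
        assert ll == pytest.approx(math.log(0.875), abs=1e-10)

    def test_additivity_over_rows(self, tiny_obs, centered_params):
        total = loglik(centered_params, tiny_obs)
        cp_rows = []
        from dziop import category_probs
        probs = category_probs(centered_params, tiny_obs).probs
        by_hand = float(np.log(probs[np.arange(tiny_obs.n),
                                      tiny_obs.y]).sum())
        assert total == pytest.approx(by_hand, abs=1e-10)

    def test_duplicating_rows_doubles_loglik(self, tiny_spec, centered_params):
        df = pd.DataFrame({"y": [0, 1, 2, 3], "x": [0.0, 0.5, -0.5, 1.0]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs1 = build_design(df, tiny_spec)
            obs2 = build_design(pd.concat([df, df], ignore_index=True),
                                tiny_spec)
        assert loglik(centered_params, obs2) == pytest.approx(
            2.0 * loglik(centered_params, obs1), rel=1e-12)


class TestParamTransform:
    def test_pack_unpack_roundtrip(self, tiny_obs):
        tr = transform_for(tiny_obs, "DZIOPC")
        p = ParameterSet(beta_r=[0.3, -0.2], beta_m=[1.0, 0.1],
                         beta_y=[-0.4, 0.6], mu=[0.5, 1.7], rho_rm=-0.55,
                         rho_ry=0.2, rho_my=0.1, variant="DZIOPC")
        q = tr.unpack(tr.pack(p))
        assert np.allclose(q.beta_r, p.beta_r)
        assert np.allclose(q.mu, p.mu)
        assert np.allclose(q.rho, p.rho, atol=1e-10)

    def test_any_theta_gives_valid_parameters(self, tiny_obs):
        tr = transform_for(tiny_obs, "DZIOPC")
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = tr.unpack(rng.normal(0, 2, tr.n_params))
            p.validate()  # ordered thresholds, PD correlation matrix


class TestStartingValues:
    def test_thresholds_strictly_increasing(self, dziop_sim):
        _, _, _, obs = dziop_sim
        for variant in ("OP", "ZIOP", "DZIOP"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = starting_values(obs, variant)
            assert s.mu[0] > 0 and np.all(np.diff(s.mu) > 0)

    def test_correlated_start_equals_independent_with_zero_rho(self, dziop_sim):
        _, _, _, obs = dziop_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s_i = starting_values(obs, "DZIOP")
            s_c = starting_values(obs, "DZIOPC")
        assert np.allclose(s_i.beta_r, s_c.beta_r)
        assert np.allclose(s_i.beta_y, s_c.beta_y)
        assert np.all(s_c.rho == 0.0)

    def test_op_start_has_no_hurdle_coefficients(self, dziop_sim):
        _, _, _, obs = dziop_sim
        s = starting_values(obs, "OP")
        assert s.beta_r.size == 0 and s.beta_m.size == 0


class TestFit:
    def test_fit_improves_on_start_and_converges(self, dziop_fit_small,
                                                 dziop_sim):
        cfg, _, _, obs = dziop_sim
        res = dziop_fit_small
        assert res.converged
        assert res.gradient_norm <= 1e-4
        start = starting_values(obs, "DZIOP")
        assert res.loglik >= loglik(start, obs)

    def test_reproducible_bit_identical(self, dziop_sim):
        _, _, _, obs = dziop_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = fit(obs, "OP", compute_cov=False)
            r2 = fit(obs, "OP", compute_cov=False)
        assert r1.loglik == r2.loglik
        assert np.array_equal(r1.estimates, r2.estimates)

    def test_nested_model_likelihood_ordering(self, dziop_sim,
                                              dziop_fit_small):
        """The double-hurdle model nests the single hurdle and plain OP."""
        _, _, _, obs = dziop_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll_op = fit(obs, "OP", compute_cov=False).loglik
            ll_ziop = fit(obs, "ZIOP", compute_cov=False).loglik
        assert dziop_fit_small.loglik >= ll_ziop - 1e-4
        assert ll_ziop >= ll_op - 1e-4

    def test_dziopc_with_frozen_rho_matches_dziop(self, dziop_sim,
                                                  dziop_fit_small):
        _, _, _, obs = dziop_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_c = fit(obs, "DZIOPC", fix_rho=True, compute_cov=False,
                        n_draws=64, presolve_draws=0)
        assert res_c.loglik == pytest.approx(dziop_fit_small.loglik,
                                             rel=1e-6)

    def test_misreporting_variant_requires_xm(self):
        df = pd.DataFrame({"y": [0, 1, 2, 3] * 4,
                           "x": np.linspace(-1, 1, 16)})
        spec = EquationSpec("y", ["x"], [], ["x"], intercept_m=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs = build_design(df, spec)
        with pytest.raises(ValueError, match="misreporting"):
            fit(obs, "DZIOP")


class TestCovariances:
    def test_sandwich_symmetric_nonnegative_diagonal(self, dziop_fit_small):
        C = dziop_fit_small.cov_robust
        assert C is not None
        assert np.abs(C - C.T).max() < 1e-10
        assert np.all(np.diag(C) >= 0.0)
        H = dziop_fit_small.cov_hessian
        assert np.abs(H - H.T).max() < 1e-10

    def test_se_scale_shrinks_with_sample_size(self):
        """Standard errors should fall roughly like 1/sqrt(n)."""
        ses = {}
        for n in (1200, 4800):
            cfg = condensed_preset(n=n, seed=9, correlated=False)
            table, _ = simulate_dataset(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                obs = build_design(table, cfg.spec, "DZIOP")
                res = fit(obs, "DZIOP", seed=2)
            ses[n] = res.se_robust
        ratio = np.median(ses[1200] / ses[4800])
        assert 1.3 < ratio < 3.2  # ~2 expected for a 4x larger sample


class TestLRTest:
    def _mk(self, variant, ll, k):
        return FitResult(params=None, loglik=ll, param_names=["p"] * k,
                         estimates=np.zeros(k), cov_robust=None,
                         cov_hessian=None, gradient_norm=0.0, n_iterations=1,
                         converged=True, n_obs=100, variant=variant)

    def test_equal_logliks_give_zero_statistic(self):
        t = lr_independence_test(self._mk("DZIOPC", -50.0, 13),
                                 self._mk("DZIOP", -50.0, 10))
        assert t.statistic == 0.0
        assert t.p_value == pytest.approx(1.0)

    def test_chi_square_tail_value(self):
        t = lr_independence_test(self._mk("DZIOPC", -100.0, 13),
                                 self._mk("DZIOP", -102.0, 10))
        assert t.statistic == pytest.approx(4.0)
        assert t.df == 3
        assert t.p_value == pytest.approx(0.2615, abs=2e-4)

    def test_noise_induced_negative_statistic_clipped(self):
        t = lr_independence_test(self._mk("DZIOPC", -102.5, 13),
                                 self._mk("DZIOP", -102.0, 10))
        assert t.statistic == 0.0

    def test_mismatched_pair_raises(self):
        with pytest.raises(ValueError):
            lr_independence_test(self._mk("DZIOP", -50.0, 10),
                                 self._mk("DZIOPC", -50.0, 13))
        with pytest.raises(ValueError, match="specification"):
            lr_independence_test(self._mk("DZIOPC", -50.0, 14),
                                 self._mk("DZIOP", -50.0, 10))
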