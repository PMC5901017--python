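"""Design construction, category probabilities, zero decomposition."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from dziop import (EquationSpec, ParameterSet, build_design, category_probs,
                   zero_components)
from dziop.model_core import _row_thresholds


class TestBuildDesign:
    def test_intercept_prepended(self, tiny_obs):
        assert tiny_obs.Xr.shape[1] == 2
        assert np.all(tiny_obs.Xr[:, 0] == 1.0)
        assert tiny_obs.names_r == ["const", "x"]

    def test_j_inferred_from_four_categories(self, tiny_obs):
        assert tiny_obs.J == 3
        p = ParameterSet(beta_r=[0, 0], beta_m=[0, 0], beta_y=[0, 0],
                         mu=[0.8, 1.6], variant="DZIOP")
        assert category_probs(p, tiny_obs).probs.shape == (12, 4)

    def test_missing_column_named_in_error(self, tiny_spec):
        df = pd.DataFrame({"y": [0, 1, 2], "z": [1.0, 2.0, 3.0]})
        with pytest.raises(KeyError, match="x"):
            build_design(df, tiny_spec)

    def test_non_integer_outcome_rejected(self, tiny_spec):
        df = pd.DataFrame({"y": [0.0, 1.5, 2.0], "x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="integer"):
            build_design(df, tiny_spec)

    def test_negative_outcome_rejected(self, tiny_spec):
        df = pd.DataFrame({"y": [0, -1, 2], "x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            build_design(df, tiny_spec)

    def test_empty_category_warns(self, tiny_spec):
        df = pd.DataFrame({"y": [0, 1, 3, 3], "x": [0.0, 1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="no observations"):
            build_design(df, tiny_spec)

    def test_missing_exclusion_restriction_warns(self):
        df = pd.DataFrame({"y": [0, 1, 2, 3], "x": [0.0, 1.0, 2.0, 3.0]})
        spec = EquationSpec("y", ["x"], ["x"], ["x"])
        with pytest.warns(UserWarning, match="exclusion"):
            build_design(df, spec, "DZIOP")


class TestParameterSet:
    def test_threshold_ordering_enforced(self):
        p = ParameterSet(beta_r=[0], beta_m=[0], beta_y=[0], mu=[1.0, 0.5],
                         variant="DZIOP")
        with pytest.raises(ValueError, match="mu"):
            p.validate()
        p2 = ParameterSet(beta_r=[0], beta_m=[0], beta_y=[0], mu=[-0.1, 0.5],
                          variant="DZIOP")
        with pytest.raises(ValueError):
            p2.validate()

    def test_correlations_forbidden_without_correlated_variant(self):
        p = ParameterSet(beta_r=[0], beta_m=[0], beta_y=[0], mu=[0.5, 1.0],
                         rho_rm=0.3, variant="DZIOP")
        with pytest.raises(ValueError, match="zero correlations"):
            p.validate()

    def test_non_pd_omega_rejected(self):
        p = ParameterSet(beta_r=[0], beta_m=[0], beta_y=[0], mu=[0.5, 1.0],
                         rho_rm=0.9, rho_ry=0.9, rho_my=-0.9,
                         variant="DZIOPC")
        with pytest.raises(ValueError, match="positive definite"):
            p.validate()


class TestCategoryProbs:
    def test_hand_evaluated_zero_probability(self, tiny_obs, centered_params):
        # all three indices zero: 0.5 + 0.5*0.5 + 0.5*0.5*0.5 = 0.875
        cp = category_probs(centered_params, tiny_obs)
        x0 = np.where(tiny_obs.Xr[:, 1] == 0.0)[0]
        # use an x value of ~0: coefficients on x are zero anyway
        assert cp.probs[0, 0] == pytest.approx(0.875, abs=1e-12)

    def test_degenerate_hurdles_reduce_to_op(self, tiny_obs):
        op = ParameterSet(beta_r=np.empty(0), beta_m=np.empty(0),
                          beta_y=[0.2, 0.5], mu=[0.8, 1.6], variant="OP")
        dz = ParameterSet(beta_r=[10.0, 0.0], beta_m=[10.0, 0.0],
                          beta_y=[0.2, 0.5], mu=[0.8, 1.6], variant="DZIOP")
        p_op = category_probs(op, tiny_obs).probs
        p_dz = category_probs(dz, tiny_obs).probs
        assert np.abs(p_op - p_dz).max() < 1e-8

    def test_nesting_chain(self, tiny_obs):
        base = dict(beta_y=[0.2, 0.5], mu=[0.8, 1.6])
        dziop = ParameterSet(beta_r=[0.4, -0.3], beta_m=[10.0, 0.0], **base,
                             variant="DZIOP")
        ziop = ParameterSet(beta_r=[0.4, -0.3], beta_m=np.empty(0), **base,
                            variant="ZIOP")
        assert np.abs(category_probs(dziop, tiny_obs).probs
                      - category_probs(ziop, tiny_obs).probs).max() < 1e-8
        ziop_deg = ParameterSet(beta_r=[10.0, 0.0], beta_m=np.empty(0),
                                **base, variant="ZIOP")
        op = ParameterSet(beta_r=np.empty(0), beta_m=np.empty(0), **base,
                          variant="OP")
        assert np.abs(category_probs(ziop_deg, tiny_obs).probs
                      - category_probs(op, tiny_obs).probs).max() < 1e-8

    def test_correlated_at_zero_rho_equals_independent(self, tiny_obs):
        kw = dict(beta_r=[0.3, 0.5], beta_m=[1.0, -0.2], beta_y=[0.2, 0.4],
                  mu=[0.8, 1.6])
        dz = ParameterSet(**kw, variant="DZIOP")
        dzc = ParameterSet(**kw, variant="DZIOPC")
        p_q = category_probs(dzc, tiny_obs, method="quadrature").probs
        p_g = category_probs(dzc, tiny_obs, method="ghk", n_draws=200,
                             seed=0).probs
        p_i = category_probs(dz, tiny_obs).probs
        assert np.abs(p_q - p_i).max() < 1e-10
        # at rho=0 the GHK conditioning is exact, not just unbiased
        assert np.abs(p_g - p_i).max() < 1e-12

    def test_ghk_and_quadrature_agree_when_correlated(self, tiny_obs):
        p = ParameterSet(beta_r=[0.3, 0.5], beta_m=[1.0, -0.2],
                         beta_y=[0.2, 0.4], mu=[0.8, 1.6], rho_rm=-0.5,
                         rho_ry=0.1, rho_my=0.3, variant="DZIOPC")
        q = category_probs(p, tiny_obs, method="quadrature").probs
        g = category_probs(p, tiny_obs, method="ghk", n_draws=2000,
                           seed=3).probs
        assert np.abs(q - g).max() < 5e-4

    def test_dimension_mismatch_raises(self, tiny_obs):
        p = ParameterSet(beta_r=[0.1], beta_m=[0, 0], beta_y=[0, 0],
                         mu=[0.8, 1.6], variant="DZIOP")
        with pytest.raises(ValueError, match="beta_r"):
            category_probs(p, tiny_obs)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"y": np.tile([0, 1, 2, 3], 3),
                           "x": rng.normal(0, 1, 12)})
        spec = EquationSpec("y", ["x"], ["x"], ["x"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs = build_design(df, spec)
        t = rng.uniform(-0.9, 0.9, 3)
        r12, r13 = t[0], t[1]
        r23 = r12 * r13 + t[2] * np.sqrt((1 - r12 ** 2) * (1 - r13 ** 2))
        p = ParameterSet(beta_r=rng.normal(0, 1, 2), beta_m=rng.normal(0, 1, 2),
                         beta_y=rng.normal(0, 1, 2),
                         mu=np.cumsum(rng.uniform(0.2, 1.0, 2)),
                         rho_rm=r12, rho_ry=r13, rho_my=r23,
                         variant="DZIOPC")
        cp = category_probs(p, obs)  # validates sums to 1 within 1e-10
        assert np.all(cp.probs >= 0.0) and np.all(cp.probs <= 1.0)


class TestGopThresholds:
    def test_row_thresholds_strictly_increasing_for_any_coefficients(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": np.tile([0, 1, 2, 3], 5),
                           "x": rng.normal(0, 1, 20),
                           "z": rng.normal(0, 3, 20)})
        spec = EquationSpec("y", [], [], ["x"], threshold_columns=["z"])
        obs = build_design(df, spec)
        for _ in range(20):
            p = ParameterSet(beta_r=np.empty(0), beta_m=np.empty(0),
                             beta_y=rng.normal(0, 1, 2),
                             mu=np.cumsum(rng.uniform(0.1, 1.0, 2)),
                             gamma=rng.normal(0, 2, (2, 1)), variant="GOP")
            mu_rows = _row_thresholds(p, obs)
            assert np.all(mu_rows[:, 0] > 0)
            assert np.all(np.diff(mu_rows, axis=1) > 0)
            category_probs(p, obs)  # normalization still holds

    def test_zero_gamma_matches_plain_op(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": np.tile([0, 1, 2, 3], 5),
                           "x": rng.normal(0, 1, 20),
                           "z": rng.normal(0, 1, 20)})
        spec = EquationSpec("y", [], [], ["x"], threshold_columns=["z"])
        obs = build_design(df, spec)
        common = dict(beta_r=np.empty(0), beta_m=np.empty(0),
                      beta_y=[0.3, 0.4], mu=[0.7, 1.5])
        gop = ParameterSet(**common, gamma=np.zeros((2, 1)), variant="GOP")
        op = ParameterSet(**common, variant="OP")
        assert np.abs(category_probs(gop, obs).probs
                      - category_probs(op, obs).probs).max() < 1e-12


class TestZeroComponents:
    def test_hand_evaluated_triple(self, tiny_obs, centered_params):
        comp = zero_components(centered_params, tiny_obs)
        assert comp[0] == pytest.approx([0.5, 0.25, 0.125], abs=1e-12)

    def test_components_sum_to_zero_probability(self, tiny_obs):
        p = ParameterSet(beta_r=[0.3, 0.5], beta_m=[1.0, -0.2],
                         beta_y=[0.2, 0.4], mu=[0.8, 1.6], rho_rm=-0.5,
                         rho_ry=0.1, rho_my=0.3, variant="DZIOPC")
        comp = zero_components(p, tiny_obs)
        p0 = category_probs(p, tiny_obs).probs[:, 0]
        assert np.abs(comp.sum(axis=1) - p0).max() < 1e-10
        assert np.all(comp >= 0.0)

    def test_degenerate_hurdles_leave_only_true_zeros(self, tiny_obs):
        p = ParameterSet(beta_r=[10.0, 0.0], beta_m=[10.0, 0.0],
                         beta_y=[0.2, 0.4], mu=[0.8, 1.6], variant="DZIOP")
        comp = zero_components(p, tiny_obs)
        ay = tiny_obs.Xy @ p.beta_y
        assert np.abs(comp[:, 0]).max() < 1e-8
        assert np.abs(comp[:, 1]).max() < 1e-8
        assert comp[:, 2] == pytest.approx(norm.cdf(-ay), abs=1e-8)

    def test_unsupported_variant_raises(self, tiny_obs):
        p = ParameterSet(beta_r=[0, 0], beta_m=np.empty(0), beta_y=[0, 0],
                         mu=[0.8, 1.6], variant="ZIOP")
        with pytest.raises(ValueError, match="misreporting"):
            zero_components(p, tiny_obs)
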