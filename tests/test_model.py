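"""Closed-form mixture density, tdr, and posterior moments of delta given z."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from gwasmix import (
    ModelParams,
    SnpContext,
    expected_components,
    expected_delta_sq,
    heterozygosity,
    mixture_cdf,
    mixture_pdf,
    overestimation_factor,
    posterior_moments,
    posterior_pdf,
    power_given_delta,
    scaled_variances,
    tdr,
)

NULL_ONLY = ModelParams(pi1=0.0, sigma0_sq=1.0, sigma_a_sq=0.0, sigma_b_sq=0.0)
UNIT_CTX = SnpContext(n_eff=1.0, het=0.5)

param_strategy = st.builds(
    ModelParams,
    pi1=st.floats(0.0, 1.0),
    sigma0_sq=st.floats(0.1, 4.0),
    sigma_a_sq=st.floats(0.0, 1e-4),
    sigma_b_sq=st.floats(0.0, 1e-3),
)
ctx_strategy = st.builds(
    SnpContext,
    n_eff=st.floats(100.0, 1e5),
    het=st.floats(0.01, 0.5),
)


class TestHeterozygosity:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.5), (0.0, 0.0), (0.1, 0.18)])
    def test_values(self, p, expected):
        assert heterozygosity(p) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0))
    @settings(derandomize=True)
    def test_symmetric_in_allele_swap(self, p):
        assert heterozygosity(p) == pytest.approx(heterozygosity(1.0 - p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            heterozygosity(1.2)


class TestScaledVariances:
    def test_zero_per_allele_variances(self):
        sv = scaled_variances(NULL_ONLY, SnpContext(n_eff=1e4, het=0.3))
        assert sv.sigma1_sq == 0.0 and sv.sigma2_sq == 0.0

    def test_direct_product(self):
        p = ModelParams(pi1=0.01, sigma0_sq=1.0, sigma_a_sq=1e-4, sigma_b_sq=0.0)
        sv = scaled_variances(p, SnpContext(n_eff=1e4, het=0.5))
        assert sv.sigma1_sq == pytest.approx(0.5)

    def test_schizophrenia_scale(self, scz_params):
        # independent direct evaluation: sigma_a^2*N*H and sigma_b^2*N*H
        sv = scaled_variances(scz_params, SnpContext(n_eff=34000, het=0.3))
        assert sv.sigma1_sq == pytest.approx(0.331398, rel=1e-12)
        assert sv.sigma2_sq == pytest.approx(4.08, rel=1e-12)


class TestMixturePdfCdf:
    def test_standard_normal_at_zero(self):
        assert mixture_pdf(0.0, NULL_ONLY, UNIT_CTX) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi), rel=1e-9
        )

    def test_degenerate_arms_coincide(self):
        base = dict(sigma0_sq=1.2, sigma_a_sq=2e-5, sigma_b_sq=0.0)
        ctx = SnpContext(n_eff=2e4, het=0.4)
        z = np.linspace(-4, 4, 9)
        f0 = mixture_pdf(z, ModelParams(pi1=0.0, **base), ctx)
        f1 = mixture_pdf(z, ModelParams(pi1=1.0, **base), ctx)
        np.testing.assert_allclose(f0, f1, rtol=1e-14)

    def test_frozen_value(self, scz_params, ctx_nh_1e4):
        # direct evaluation of the two-Gaussian sum in an independent script
        assert mixture_pdf(2.0, scz_params, ctx_nh_1e4) == pytest.approx(
            0.07971687589852011, rel=1e-12
        )

    @given(params=param_strategy, ctx=ctx_strategy)
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_integrates_to_one(self, params, ctx):
        total, _ = quad(lambda z: mixture_pdf(z, params, ctx), -np.inf, np.inf)
        assert abs(total - 1.0) < 1e-8

    def test_cdf_limits_and_symmetry(self, scz_params, ctx_nh_1e4):
        assert mixture_cdf(0.0, scz_params, ctx_nh_1e4) == pytest.approx(0.5)
        assert mixture_cdf(60.0, scz_params, ctx_nh_1e4) == pytest.approx(1.0)
        z = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(
            mixture_cdf(-z, scz_params, ctx_nh_1e4),
            1.0 - mixture_cdf(z, scz_params, ctx_nh_1e4),
            atol=1e-14,
        )
        grid = mixture_cdf(np.linspace(-8, 8, 200), scz_params, ctx_nh_1e4)
        assert np.all(np.diff(grid) >= 0)

    def test_null_tail_matches_genome_wide_threshold(self):
        # one-tailed p = 5e-8 corresponds to z_t = -5.33 under the null arm
        assert mixture_cdf(-5.33, NULL_ONLY, UNIT_CTX) == pytest.approx(5e-8, rel=0.02)


class TestTdr:
    def test_zero_when_no_sparse_class(self, ctx_nh_1e4):
        assert tdr(3.0, NULL_ONLY, ctx_nh_1e4) == 0.0

    def test_constant_when_arms_coincide(self, ctx_nh_1e4):
        p = ModelParams(pi1=0.3, sigma0_sq=1.0, sigma_a_sq=1e-5, sigma_b_sq=0.0)
        z = np.linspace(-6, 6, 13)
        np.testing.assert_allclose(tdr(z, p, ctx_nh_1e4), 0.3, rtol=1e-12)

    def test_frozen_value(self, scz_params, ctx_nh_1e4):
        assert tdr(5.0, scz_params, ctx_nh_1e4) == pytest.approx(
            0.9505557287533525, rel=1e-12
        )

    @given(params=param_strategy, ctx=ctx_strategy, z=st.floats(-40, 40))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bounded_symmetric_no_underflow(self, params, ctx, z):
        t = tdr(z, params, ctx)
        assert 0.0 <= t <= 1.0 and np.isfinite(t)
        assert t == pytest.approx(tdr(-z, params, ctx), abs=1e-12)

    def test_monotone_in_abs_z_with_sparse_arm(self, scz_params, ctx_nh_1e4):
        z = np.linspace(0, 10, 41)
        t = tdr(z, scz_params, ctx_nh_1e4)
        assert np.all(np.diff(t) >= 0)


class TestPosterior:
    def test_means_proportional_to_z(self, scz_params, ctx_nh_1e4):
        pm = posterior_moments(0.0, scz_params, ctx_nh_1e4)
        assert pm.mu_u == 0.0 and pm.mu_s == 0.0
        assert 0.0 < pm.var_u < pm.var_s

    def test_shrinkage_vanishes_without_noise(self):
        p = ModelParams(pi1=0.05, sigma0_sq=1e-12, sigma_a_sq=1e-5, sigma_b_sq=1e-4)
        pm = posterior_moments(2.5, p, SnpContext(n_eff=1e4, het=0.3))
        assert pm.mu_u == pytest.approx(2.5, rel=1e-6)
        assert pm.mu_s == pytest.approx(2.5, rel=1e-8)

    def test_frozen_moments(self, scz_params, ctx_nh_1e4):
        pm = posterior_moments(3.0, scz_params, ctx_nh_1e4)
        assert pm.tdr == pytest.approx(0.18820683531121868, rel=1e-12)
        assert pm.mu_u == pytest.approx(0.7203480019156069, rel=1e-12)
        assert pm.mu_s == pytest.approx(2.423774951915677, rel=1e-12)
        assert pm.var_u == pytest.approx(0.24688631139253978, rel=1e-12)
        assert pm.var_s == pytest.approx(0.8307052368199638, rel=1e-12)

    def test_pdf_single_arm_when_no_sparse_class(self, ctx_nh_1e4):
        p = ModelParams(pi1=0.0, sigma0_sq=1.0, sigma_a_sq=2e-5, sigma_b_sq=0.0)
        pm = posterior_moments(2.0, p, ctx_nh_1e4)
        delta = np.linspace(-2, 4, 7)
        expected = np.exp(-0.5 * (delta - pm.mu_u) ** 2 / pm.var_u) / np.sqrt(
            2 * np.pi * pm.var_u
        )
        np.testing.assert_allclose(
            posterior_pdf(delta, 2.0, p, ctx_nh_1e4), expected, rtol=1e-12
        )

    def test_pdf_frozen_value(self, scz_params, ctx_nh_1e4):
        assert posterior_pdf(2.0, 4.0, scz_params, ctx_nh_1e4) == pytest.approx(
            0.14271955044595147, rel=1e-12
        )

    @pytest.mark.parametrize("z", [0.0, 1.0, 3.0, 5.5])
    def test_pdf_normalization_and_moments(self, z, scz_params, ctx_nh_1e4):
        total, _ = quad(
            lambda d: posterior_pdf(d, z, scz_params, ctx_nh_1e4), -np.inf, np.inf
        )
        assert abs(total - 1.0) < 1e-8
        mean, _ = quad(
            lambda d: d * posterior_pdf(d, z, scz_params, ctx_nh_1e4), -np.inf, np.inf
        )
        second, _ = quad(
            lambda d: d * d * posterior_pdf(d, z, scz_params, ctx_nh_1e4),
            -np.inf,
            np.inf,
        )
        e_a, e_b, e_u, e_s = expected_components(z, scz_params, ctx_nh_1e4)
        assert mean == pytest.approx(float(e_u + e_s), abs=1e-9)
        assert second == pytest.approx(
            expected_delta_sq(z, scz_params, ctx_nh_1e4), rel=1e-6, abs=1e-9
        )


class TestExpectedComponents:
    def test_zero_at_origin(self, scz_params, ctx_nh_1e4):
        assert expected_components(0.0, scz_params, ctx_nh_1e4) == (0.0, 0.0, 0.0, 0.0)

    def test_sparse_components_vanish_without_sparse_class(self, ctx_nh_1e4):
        p = ModelParams(pi1=0.0, sigma0_sq=1.0, sigma_a_sq=2e-5, sigma_b_sq=1e-4)
        e_a, e_b, e_u, e_s = expected_components(2.0, p, ctx_nh_1e4)
        assert e_b == 0.0 and e_s == 0.0
        assert e_a == pytest.approx(float(e_u))

    def test_frozen_values(self, scz_params, ctx_nh_1e4):
        e_a, e_b, e_u, e_s = expected_components(2.0, scz_params, ctx_nh_1e4)
        assert e_a == pytest.approx(0.46046658886427977, rel=1e-12)
        assert e_b == pytest.approx(0.08231609871990912, rel=1e-12)
        assert e_u == pytest.approx(0.45378046374575515, rel=1e-12)
        assert e_s == pytest.approx(0.08900222383843376, rel=1e-12)

    @given(params=param_strategy, ctx=ctx_strategy, z=st.floats(-8, 8))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_decompositions_agree(self, params, ctx, z):
        e_a, e_b, e_u, e_s = expected_components(z, params, ctx)
        assert float(e_a + e_b) == pytest.approx(float(e_u + e_s), abs=1e-12, rel=1e-10)


class TestExpectedDeltaSq:
    def test_no_shrinkage_limit(self):
        p = ModelParams(pi1=0.0, sigma0_sq=1e-12, sigma_a_sq=1e-5, sigma_b_sq=0.0)
        assert expected_delta_sq(3.0, p, SnpContext(n_eff=1e4, het=0.3)) == pytest.approx(
            9.0, rel=1e-6
        )

    def test_origin_value_is_variance_mixture(self, scz_params, ctx_nh_1e4):
        pm = posterior_moments(0.0, scz_params, ctx_nh_1e4)
        expected = (1 - pm.tdr) * pm.var_u + pm.tdr * pm.var_s
        assert expected_delta_sq(0.0, scz_params, ctx_nh_1e4) == pytest.approx(
            float(expected), rel=1e-12
        )

    def test_frozen_value(self, scz_params, ctx_nh_1e4):
        assert expected_delta_sq(5.33, scz_params, ctx_nh_1e4) == pytest.approx(
            19.026546813925275, rel=1e-12
        )

    @given(params=param_strategy, ctx=ctx_strategy, z=st.floats(-8, 8))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_exceeds_squared_mean(self, params, ctx, z):
        _, _, e_u, e_s = expected_components(z, params, ctx)
        assert expected_delta_sq(z, params, ctx) >= float(e_u + e_s) ** 2 - 1e-12


class TestOverestimationFactor:
    def test_undefined_at_zero(self, scz_params, ctx_nh_1e4):
        with pytest.raises(ValueError):
            overestimation_factor(0.0, scz_params, ctx_nh_1e4)

    def test_approaches_one_without_noise(self):
        p = ModelParams(pi1=0.0, sigma0_sq=1e-12, sigma_a_sq=1e-5, sigma_b_sq=0.0)
        assert overestimation_factor(3.0, p, SnpContext(n_eff=1e4, het=0.3)) == pytest.approx(
            1.0, rel=1e-6
        )

    def test_frozen_value(self, scz_params, ctx_nh_1e4):
        assert overestimation_factor(5.33, scz_params, ctx_nh_1e4) == pytest.approx(
            1.4931190760904602, rel=1e-12
        )


class TestPowerGivenDelta:
    def test_null_power_is_alpha(self):
        assert power_given_delta(0.0, -1.6448536269514729, NULL_ONLY) == pytest.approx(
            0.05, rel=1e-9
        )

    def test_saturates_for_large_effects(self):
        assert power_given_delta(50.0, -1.645, NULL_ONLY) == pytest.approx(1.0)

    def test_frozen_value(self, scz_params):
        assert power_given_delta(3.0, -1.645, scz_params) == pytest.approx(
            0.909273060658127, rel=1e-12
        )

    def test_rejects_positive_threshold(self, scz_params):
        with pytest.raises(ValueError):
            power_given_delta(1.0, 1.645, scz_params)
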