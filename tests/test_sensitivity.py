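"""Analytic measurement-error results and the reliability ratio."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import causaldir as cd
from causaldir.exceptions import DomainError


class TestAttenuationD:
    def test_no_imprecision_gives_one(self):
        assert cd.attenuation_D(1.0, 1.0, 0.0) == 1.0

    def test_scale_only_transformation_gives_one(self):
        # rescaling without added noise does not attenuate
        assert cd.attenuation_D(5.0, 1.0, 0.0) == 1.0

    def test_equal_signal_and_noise_gives_half(self):
        assert cd.attenuation_D(1.0, 1.0, 1.0) == pytest.approx(0.5)

    @settings(derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=0.0, max_value=10),
    )
    def test_bounded_in_unit_interval(self, beta, var_x, var_eps):
        d = cd.attenuation_D(beta, var_x, var_eps)
        assert 0.0 < d <= 1.0
        if var_eps == 0.0:
            assert d == 1.0
        elif var_eps > 1e-6:
            assert d < 1.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            cd.attenuation_D(1.0, 0.0, 1.0)
        with pytest.raises(DomainError):
            cd.attenuation_D(0.0, 1.0, 1.0)


class TestResidualCovBias:
    def test_zero_when_no_attenuation(self):
        assert cd.residual_cov_bias(0.3, 1.0, 1.0, 0.5, 1.0) == 0.0

    def test_sign_flips_with_causal_effect(self):
        a = cd.residual_cov_bias(0.3, 1.0, 1.0, 0.5, 0.5)
        b = cd.residual_cov_bias(0.3, -1.0, 1.0, 0.5, 0.5)
        assert b == -a

    @pytest.mark.parametrize("sigma2_mx", [0.25, 1.0, 4.0])
    @pytest.mark.parametrize("beta_x", [0.5, 1.0, 2.0])
    def test_matches_simulated_conditional_covariance(self, sigma2_mx, beta_x):
        """The analytic residual covariance equals the large-sample empirical
        cov(g, y_o - yhat_o) where yhat_o is fitted from the observed
        exposure, within 3 Monte-Carlo standard errors."""
        n = 100_000
        beta_g, beta_my, maf = 0.3162, 1.0, 0.5
        rng = np.random.default_rng([37, int(sigma2_mx * 4), int(beta_x * 2)])
        g = rng.binomial(2, maf, n).astype(float)
        x = beta_g * g + rng.normal(size=n)
        y = beta_x * x + rng.normal(size=n)
        x_o = x + rng.normal(0, math.sqrt(sigma2_mx), n)
        y_o = beta_my * y
        var_x = beta_g**2 * 2 * maf * (1 - maf) + 1.0
        D = cd.attenuation_D(1.0, var_x, sigma2_mx)
        expected = cd.residual_cov_bias(beta_g, beta_x, beta_my, 2 * maf * (1 - maf), D)
        slope = np.cov(x_o, y_o)[0, 1] / np.var(x_o, ddof=1)
        resid = y_o - y_o.mean() - slope * (x_o - x_o.mean())
        gc = g - g.mean()
        emp = float(gc @ resid) / (n - 1)
        mc_se = np.std(gc * resid) / math.sqrt(n)
        assert abs(emp - expected) < 3 * mc_se


class TestDStatistic:
    def test_perfect_exposure_measurement_never_negative(self):
        grid = np.linspace(-1, 1, 41)
        for rho_xy in grid:
            for rho_yyo in np.linspace(0, 1, 21):
                assert cd.d_statistic(1.0, rho_xy, rho_yyo) >= 0.0

    def test_simple_arithmetic(self):
        assert cd.d_statistic(0.5, 0.9, 1.0) == pytest.approx(-0.4)

    def test_negative_region_shrinks_with_weaker_trait_correlation(self):
        def neg_area(rho_xy):
            u = np.linspace(0, 1, 21)
            v = np.linspace(0, 1, 21)
            uu, vv = np.meshgrid(u, v)
            return np.mean(uu - rho_xy * vv < 0)

        areas = [neg_area(r) for r in (0.9, 0.6, 0.3, 0.1)]
        assert all(a > b for a, b in zip(areas, areas[1:]))


class TestPredictedSurface:
    def test_no_error_point_returns_observed_difference(self):
        z = cd.predicted_surface(0.3, 0.2, cd.MeasurementErrorPoint(1.0, 1.0))
        assert z == pytest.approx(0.2 - 0.3)

    def test_symmetric_point_with_equal_observations_is_zero(self):
        z = cd.predicted_surface(0.3, 0.3, cd.MeasurementErrorPoint(0.7, 0.7))
        assert z == pytest.approx(0.0)

    def test_boundary_point_corrects_to_unit_correlation(self):
        r_gx = 0.25
        z = cd.predicted_surface(r_gx, 0.1, cd.MeasurementErrorPoint(r_gx, 1.0))
        # corrected rho_gx = 1 at the admissible lower bound
        assert z == pytest.approx(0.1 - 1.0)

    def test_point_below_bound_rejected(self):
        with pytest.raises(DomainError):
            cd.predicted_surface(0.3, 0.1, cd.MeasurementErrorPoint(0.2, 1.0))

    def test_sign_agrees_with_steiger_on_population_correlations(self):
        """Population-level oracle: at every admissible grid point the sign
        of the predicted surface matches the direction a one-sample Steiger
        test infers from the corrected correlations."""
        r_gx_obs, r_gy_obs = 0.3, 0.2
        for u in np.linspace(r_gx_obs + 0.01, 1.0, 20):
            for v in np.linspace(r_gy_obs + 0.01, 1.0, 20):
                z = cd.predicted_surface(r_gx_obs, r_gy_obs,
                                         cd.MeasurementErrorPoint(u, v))
                r_gx_c, r_gy_c = r_gx_obs / u, r_gy_obs / v
                obs = cd.ObservedCorrelations(
                    # trait-trait correlation induced by the shared instrument,
                    # guaranteeing a positive-definite correlation matrix
                    r_gx=r_gx_c, r_gy=r_gy_c, r_xy=r_gx_c * r_gy_c, n=1000
                )
                steiger = cd.steiger_one_sample(obs)
                if z > 1e-12:
                    assert steiger.direction == "y_causes_x"
                elif z < -1e-12:
                    assert steiger.direction == "x_causes_y"


class TestReliabilityR:
    def test_worked_example_ratio(self):
        # instrument explains 1% of exposure variance, exposure explains
        # 10% of outcome variance; published ratio 4.40
        r_gx = math.sqrt(0.01)
        r_gy = r_gx * math.sqrt(0.1)
        res = cd.reliability_R(r_gx, r_gy, grid_resolution=500)
        assert res.R == pytest.approx(4.40, abs=0.05)
        assert res.direction == "x_causes_y"
        assert res.vol_support > res.vol_oppose > 0

    def test_equal_observed_correlations_give_unit_ratio(self):
        res = cd.reliability_R(0.2, 0.2)
        assert res.R == pytest.approx(1.0, abs=1e-9)

    def test_swapped_observations_give_reciprocal(self):
        a = cd.reliability_R(0.3, 0.12, grid_resolution=301)
        b = cd.reliability_R(0.12, 0.3, grid_resolution=301)
        assert a.R * b.R == pytest.approx(1.0, rel=1e-9)
        # support/oppose are relative to the inferred direction, so they swap
        assert b.vol_support == pytest.approx(a.vol_support)
        assert b.vol_oppose == pytest.approx(a.vol_oppose)

    def test_volumes_sum_to_total_integrated_surface(self):
        res = cd.reliability_R(0.25, 0.1, grid_resolution=201)
        u = np.linspace(0.25, 1, 201)
        v = np.linspace(0.1, 1, 201)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        z = (0.1 / vv) ** 2 - (0.25 / uu) ** 2
        cell = (0.75 / 200) * (0.9 / 200)
        assert res.vol_support + res.vol_oppose == pytest.approx(
            float(np.sum(np.abs(z))) * cell
        )

    def test_grid_converges_to_monte_carlo_integral(self):
        """Independent integration oracle: at high resolution the grid ratio
        approaches the Monte-Carlo estimate of the continuum volume ratio."""
        r_gx = math.sqrt(0.01)
        r_gy = r_gx * math.sqrt(0.1)
        rng = np.random.default_rng(12345)
        u = rng.uniform(r_gx, 1.0, 1_000_000)
        v = rng.uniform(r_gy, 1.0, 1_000_000)
        z = (r_gy / v) ** 2 - (r_gx / u) ** 2
        mc_ratio = -z[z < 0].sum() / z[z > 0].sum()
        res = cd.reliability_R(r_gx, r_gy, grid_resolution=4000)
        assert res.R == pytest.approx(mc_ratio, rel=0.01)

    def test_prior_hook_can_zero_the_opposing_volume(self):
        res = cd.reliability_R(
            0.3, 0.1, grid_resolution=101,
            prior=lambda u, v: ((0.1 / v) ** 2 <= (0.3 / u) ** 2).astype(float),
        )
        assert res.infinite and res.R == math.inf

    def test_observed_correlation_domain(self):
        with pytest.raises(DomainError):
            cd.reliability_R(1.0, 0.5)
        with pytest.raises(DomainError):
            cd.reliability_R(0.5, 0.0)
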