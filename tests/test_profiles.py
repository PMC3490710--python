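"""Prediction/validation profile likelihood, rescaling and thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2

from predprofile import (
    MonteCarloConfig,
    PredictionTarget,
    ScanConfig,
    ValidationSetup,
    interval_from_curve,
    ppl_scan,
    prediction_interval,
    rescale_vpl_to_ppl,
    threshold,
    validation_interval,
    vpl_scan,
)
from predprofile.estimation import Objective
from predprofile.fixtures import ABC_THETA

T0 = 5.0  # shared linear-model prediction time (matches conftest oracle)


@pytest.fixture(scope="module")
def linear_target():
    return PredictionTarget(T0, "x")


class TestThreshold:
    def test_asymptotic_is_chi2_quantile(self):
        assert threshold(0.9) == pytest.approx(2.705543, abs=1e-6)
        assert threshold(0.95) == pytest.approx(chi2.ppf(0.95, 1), abs=1e-12)

    @given(st.tuples(st.floats(0.05, 0.99), st.floats(0.05, 0.99)))
    def test_monotone_in_alpha(self, alphas):
        a, b = sorted(alphas)
        assert threshold(a) <= threshold(b)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            threshold(1.0)

    def test_montecarlo_needs_enough_replicates(self, linear, linear_data, linear_fit, linear_target):
        with pytest.raises(ValueError, match="100"):
            MonteCarloConfig(
                model=linear, data=linear_data, target=linear_target,
                fit_result=linear_fit, n_reps=50, seed=0,
            )


class TestVplScan:
    def test_optimum_preserved_at_fitted_prediction(self, linear, linear_data, linear_fit, linear_target):
        curve = vpl_scan(
            linear, linear_data, ValidationSetup(target=linear_target, SD=0.3),
            linear_fit,
        )
        assert curve.neg2PL.min() == pytest.approx(curve.neg2LL_star, abs=1e-8)
        z_hat = T0 * linear_fit.theta_hat[0]
        assert curve.grid[np.argmin(curve.neg2PL)] == pytest.approx(z_hat, abs=1e-6)

    def test_linear_curvature_is_gaussian_convolution(self, linear, linear_data, linear_fit, linear_ref, linear_target):
        curve = vpl_scan(
            linear, linear_data, ValidationSetup(target=linear_target, SD=0.3),
            linear_fit,
        )
        coeff = np.polyfit(curve.grid, curve.neg2PL, 2)[0]
        assert coeff == pytest.approx(
            linear_ref.profile_curvature_validation(), rel=1e-5
        )

    def test_abc_vpl_wider_than_ppl_everywhere(self, abc, abc_full_data, abc_full_fit):
        target = PredictionTarget(10.0, "A")
        ppl = ppl_scan(abc, abc_full_data, target, abc_full_fit)
        vpl = vpl_scan(
            abc, abc_full_data, ValidationSetup(target=target, SD=0.1), abc_full_fit
        )
        # at matched offsets from the optimum the validation profile lies
        # below the prediction profile (it spreads the same evidence over
        # the additional measurement error), so its interval is wider
        thr = threshold(0.9)
        pci = interval_from_curve(ppl, thr)
        vci = interval_from_curve(vpl, thr)
        assert vci.lower < pci.lower and vci.upper > pci.upper


class TestPplScan:
    def test_value_at_fitted_prediction_is_global_optimum(self, abc, abc_full_data, abc_full_fit):
        curve = ppl_scan(abc, abc_full_data, PredictionTarget(10.0, "A"), abc_full_fit)
        assert curve.neg2PL.min() == pytest.approx(curve.neg2LL_star, abs=1e-6)

    def test_linear_curvature_is_prediction_information(self, linear, linear_data, linear_fit, linear_ref, linear_target):
        curve = ppl_scan(linear, linear_data, linear_target, linear_fit)
        coeff = np.polyfit(curve.grid, curve.neg2PL, 2)[0]
        assert coeff == pytest.approx(
            linear_ref.profile_curvature_prediction(), rel=1e-5
        )

    def test_short_design_flat_above(self, abc, abc_short_data, abc_short_fit):
        curve = ppl_scan(abc, abc_short_data, PredictionTarget(10.0, "A"), abc_short_fit)
        assert not curve.right_crossed
        ci = interval_from_curve(curve, threshold(0.9))
        assert ci.unbounded_upper

    def test_unknown_method_rejected(self, abc, abc_full_data, abc_full_fit):
        with pytest.raises(ValueError, match="method"):
            ppl_scan(
                abc, abc_full_data, PredictionTarget(10.0, "A"), abc_full_fit,
                method="sampling",
            )


class TestRescaling:
    def test_rescale_requires_validation_curve(self, abc, abc_full_data, abc_full_fit):
        curve = ppl_scan(abc, abc_full_data, PredictionTarget(10.0, "A"), abc_full_fit)
        with pytest.raises(ValueError, match="validation"):
            rescale_vpl_to_ppl(curve, SD=0.1)

    def test_rescale_requires_recorded_responses(self):
        from predprofile import ProfileCurve

        grid = np.linspace(0, 1, 11)
        bare = ProfileCurve(
            grid=grid, neg2PL=grid**2, neg2LL_star=0.0, kind="validation",
            left_crossed=True, right_crossed=True,
        )
        with pytest.raises(ValueError, match="recorded"):
            rescale_vpl_to_ppl(bare, SD=0.1)

    def test_rescaled_validation_curve_recovers_prediction_curvature(
        self, linear, linear_data, linear_fit, linear_ref, linear_target
    ):
        # Gaussian algebra: 1/(se^2+SD^2) validation curvature maps back to
        # the 1/se^2 prediction curvature through the penalty identity
        sd = 0.3
        vpl = vpl_scan(
            linear, linear_data, ValidationSetup(target=linear_target, SD=sd),
            linear_fit,
        )
        ppl = rescale_vpl_to_ppl(vpl, SD=sd)
        coeff = np.polyfit(ppl.grid, ppl.neg2PL, 2)[0]
        assert coeff == pytest.approx(
            linear_ref.profile_curvature_prediction(), rel=1e-4
        )

    def test_correction_vanishes_at_the_optimum(self, linear, linear_data, linear_fit, linear_target):
        sd = 0.3
        vpl = vpl_scan(
            linear, linear_data, ValidationSetup(target=linear_target, SD=sd),
            linear_fit,
        )
        ppl = rescale_vpl_to_ppl(vpl, SD=sd)
        assert ppl.neg2PL.min() == pytest.approx(vpl.neg2PL.min(), abs=1e-8)


class TestIntervalProperties:
    def test_sd_to_zero_limit_vci_approaches_pci(self, linear, linear_data, linear_fit, linear_ref, linear_target):
        sd_small = linear_ref.se_prediction / 10.0
        _, pci = prediction_interval(linear, linear_data, linear_fit, linear_target, alpha=0.9)
        _, vci = validation_interval(
            linear, linear_data, linear_fit,
            ValidationSetup(target=linear_target, SD=sd_small), alpha=0.9,
        )
        expected_ratio = math.sqrt(1.0 + 0.01)  # sqrt(se^2+SD^2)/se at SD=se/10
        assert vci.width / pci.width == pytest.approx(expected_ratio, rel=1e-3)

    def test_both_intervals_contain_fitted_prediction(self, abc, abc_full_data, abc_full_fit):
        target = PredictionTarget(30.0, "B")
        z_hat = Objective(abc, abc_full_data, target=target).predict(
            abc_full_fit.theta_hat
        )
        _, pci = prediction_interval(abc, abc_full_data, abc_full_fit, target, alpha=0.9)
        _, vci = validation_interval(
            abc, abc_full_data, abc_full_fit,
            ValidationSetup(target=target, SD=0.1), alpha=0.9,
        )
        assert pci.contains(z_hat) and vci.contains(z_hat)

    def test_scan_config_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(constraint_sd_fraction=0.5)
        with pytest.raises(ValueError):
            ScanConfig(max_steps_per_side=3)


class TestMonteCarloThreshold:
    def test_linear_bootstrap_matches_chi2(self, linear, linear_data, linear_fit, linear_target):
        # for a linear model the profile statistic is exactly chi-square(1);
        # the bootstrap quantile must agree within its own sampling error
        mc = MonteCarloConfig(
            model=linear, data=linear_data, target=linear_target,
            fit_result=linear_fit, n_reps=500, seed=10,
        )
        thr_mc = threshold(0.9, method="montecarlo", mc=mc)
        # SE of the empirical 0.9-quantile of chi2(1) at n=500 is ~0.21
        assert thr_mc == pytest.approx(2.7055, abs=3 * 0.21)
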