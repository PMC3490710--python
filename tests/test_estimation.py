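"""Likelihood, fitting, parameter profiles and interval extraction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2

from predprofile import (
    Dataset,
    NoiseSpec,
    ProfileCurve,
    abc_model,
    abc_short_design,
    fit,
    interval_from_curve,
    neg2_loglik,
    profile_parameter,
    read_data_csv,
    simulate_dataset,
    write_data_csv,
)
from predprofile.fixtures import ABC_THETA, abc_full_design


class TestNeg2Loglik:
    def test_zero_at_truth_on_noisefree_data(self, abc):
        data = simulate_dataset(
            abc, ABC_THETA, abc_full_design(), NoiseSpec(sigma={"C_obs": 0.0}, seed=0)
        )
        assert neg2_loglik(abc, ABC_THETA, data) == pytest.approx(0.0, abs=1e-10)

    def test_single_standardized_residual(self, abc):
        from predprofile import ExperimentalDesign, PredictionTarget, predict

        design = ExperimentalDesign(times=(30.0,), observables=("C_obs",))
        f = predict(abc, ABC_THETA, PredictionTarget(30.0, "C"))
        records = pd.DataFrame(
            [{"time": 30.0, "observable": "C_obs", "value": f + 0.1, "sigma": 0.1}]
        )
        data = Dataset(records=records, design=design)
        assert neg2_loglik(abc, ABC_THETA, data) == pytest.approx(1.0, abs=1e-8)

    def test_equals_bruteforce_residual_sum(self, abc, abc_full_data):
        # independent summation: closed-form model response, explicit loop
        from predprofile.fixtures import abc_closed_form

        theta = np.array([0.06, 0.08, 1.1])
        total = 0.0
        for _, row in abc_full_data.records.iterrows():
            _, _, C = abc_closed_form(theta, row["time"])
            total += ((row["value"] - float(C)) / row["sigma"]) ** 2
        assert neg2_loglik(abc, theta, abc_full_data) == pytest.approx(total, rel=1e-7)

    def test_sigma_must_be_positive(self):
        from predprofile import ExperimentalDesign

        design = ExperimentalDesign(times=(1.0,), observables=("C_obs",))
        bad = pd.DataFrame(
            [{"time": 1.0, "observable": "C_obs", "value": 0.5, "sigma": 0.0}]
        )
        with pytest.raises(ValueError, match="sigma"):
            Dataset(records=bad, design=design)


class TestFit:
    def test_noise_free_recovery(self, abc):
        data = simulate_dataset(
            abc, ABC_THETA, abc_full_design(), NoiseSpec(sigma={"C_obs": 0.0}, seed=0)
        )
        result = fit(abc, data, n_starts=3, seed=2)
        assert np.max(np.abs(result.theta_hat - ABC_THETA) / ABC_THETA) < 1e-4

    def test_linear_closed_form_wlsq(self, linear, linear_data, linear_ref):
        result = fit(linear, linear_data, n_starts=3, seed=1)
        closed = linear_ref.theta_hat(linear_data.records["value"].to_numpy())
        assert result.theta_hat[0] == pytest.approx(closed, rel=1e-6)

    def test_refit_from_optimum_is_fixed_point(self, abc, abc_full_data, abc_full_fit):
        again = fit(
            abc, abc_full_data, n_starts=1, seed=9, x0=abc_full_fit.theta_hat
        )
        assert again.neg2LL_star == pytest.approx(
            abc_full_fit.neg2LL_star, abs=1e-8
        )

    def test_deterministic_given_seed(self, abc, abc_full_data):
        a = fit(abc, abc_full_data, n_starts=4, seed=5)
        b = fit(abc, abc_full_data, n_starts=4, seed=5)
        assert a.theta_hat == pytest.approx(b.theta_hat, abs=0)
        assert a.neg2LL_star == b.neg2LL_star


class TestProfileParameter:
    def test_linear_profile_quadratic_and_ci(self, linear, linear_data, linear_fit, linear_ref):
        curve, ci = profile_parameter(linear, linear_data, linear_fit, j=0, alpha=0.9)
        # quadratic profile with curvature = Fisher information sum(t^2)/sigma^2
        info = linear_ref.sum_t2 / linear_ref.sigma**2
        theta_hat = linear_fit.theta_hat[0]
        expected = linear_fit.neg2LL_star + info * (curve.grid - theta_hat) ** 2
        assert np.max(np.abs(curve.neg2PL - expected)) < 1e-6 * max(expected)
        half = math.sqrt(chi2.ppf(0.9, 1)) * linear_ref.se_theta
        assert ci.upper - ci.lower == pytest.approx(2 * half, rel=1e-4)
        assert ci.lower <= theta_hat <= ci.upper

    def test_profile_at_optimum_touches_global_fit(self, abc, abc_full_data, abc_full_fit):
        curve, ci = profile_parameter(abc, abc_full_data, abc_full_fit, j=0, alpha=0.9)
        assert curve.neg2PL.min() == pytest.approx(curve.neg2LL_star, abs=1e-6)
        assert np.all(curve.neg2PL >= curve.neg2LL_star - 1e-6)
        assert ci.lower <= abc_full_fit.theta_hat[0] <= ci.upper

    def test_short_design_concentration_scale_nonidentifiable(
        self, abc, abc_short_data, abc_short_fit
    ):
        # the short design leaves the concentration dimension (theta3) free:
        # its profile stays flat toward large values
        curve, ci = profile_parameter(abc, abc_short_data, abc_short_fit, j=2, alpha=0.9)
        assert not curve.right_crossed
        assert ci.unbounded_upper


class TestIntervalFromCurve:
    @given(
        center=st.floats(min_value=-3.0, max_value=3.0),
        width=st.floats(min_value=0.05, max_value=2.0),
        alpha=st.sampled_from([0.68, 0.9, 0.95]),
    )
    def test_quadratic_inversion_closed_form(self, center, width, alpha):
        thr = float(chi2.ppf(alpha, 1))
        grid = np.linspace(center - 3 * width, center + 3 * width, 101)
        curve = ProfileCurve(
            grid=grid,
            neg2PL=((grid - center) / width) ** 2,
            neg2LL_star=0.0,
            kind="prediction",
            left_crossed=True,
            right_crossed=True,
        )
        ci = interval_from_curve(curve, thr)
        half = width * math.sqrt(thr)
        assert ci.lower == pytest.approx(center - half, abs=1e-4 * width)
        assert ci.upper == pytest.approx(center + half, abs=1e-4 * width)

    def test_flat_tail_below_threshold_is_unbounded(self):
        grid = np.linspace(0.0, 10.0, 50)
        vals = np.where(grid < 2, (grid - 2) ** 2 * 10, 0.0)
        curve = ProfileCurve(
            grid=grid, neg2PL=vals, neg2LL_star=0.0, kind="prediction",
            left_crossed=True, right_crossed=False, right_status="unbounded",
        )
        ci = interval_from_curve(curve, 2.706)
        assert ci.unbounded_upper and not ci.unbounded_lower
        assert math.isinf(ci.upper)

    def test_zero_threshold_degenerates_to_optimum(self):
        grid = np.linspace(-1, 1, 41)
        curve = ProfileCurve(
            grid=grid, neg2PL=grid**2, neg2LL_star=0.0, kind="prediction",
            left_crossed=True, right_crossed=True,
        )
        ci = interval_from_curve(curve, 0.0)
        assert ci.lower == pytest.approx(0.0, abs=1e-6)
        assert ci.upper == pytest.approx(0.0, abs=1e-6)

    def test_curve_missing_its_optimum_is_contract_violation(self):
        grid = np.linspace(0, 1, 11)
        curve = ProfileCurve(
            grid=grid, neg2PL=5.0 + grid, neg2LL_star=0.0, kind="prediction",
            left_crossed=True, right_crossed=True,
        )
        with pytest.raises(ValueError, match="threshold level"):
            interval_from_curve(curve, 2.706)

    def test_profile_below_global_optimum_rejected(self):
        grid = np.linspace(0, 1, 11)
        with pytest.raises(ValueError, match="global optimum"):
            ProfileCurve(
                grid=grid, neg2PL=grid * 0.0, neg2LL_star=1.0, kind="prediction",
                left_crossed=True, right_crossed=True,
            )


class TestDataCsv:
    def test_round_trip(self, abc_full_data, tmp_path):
        path = tmp_path / "data.csv"
        write_data_csv(abc_full_data, path)
        assert path.read_text().splitlines()[0] == "time,observable,value,sigma"
        loaded = read_data_csv(path)
        pd.testing.assert_frame_equal(loaded.records, abc_full_data.records)
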