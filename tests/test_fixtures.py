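"""Study models, closed-form oracles and the synthetic-data generator."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2

from predprofile import (
    NoiseSpec,
    abc_full_design,
    abc_model,
    abc_short_design,
    integrate,
    linear_model,
    linear_oracle,
    mapk_design,
    mapk_model,
    simulate_dataset,
)
from predprofile.fixtures import ABC_THETA, abc_closed_form


class TestAbcFixture:
    def test_reference_parameterization(self, abc):
        assert abc.default_theta == pytest.approx([0.05, 0.1, 1.0])
        assert abc.noise_sd["C_obs"] == 0.1

    def test_design_time_grids(self):
        assert abc_full_design().times == tuple(float(t) for t in range(0, 101, 10))
        assert abc_short_design().times == tuple(float(t) for t in range(0, 21, 2))

    def test_chain_absorbs_into_c_at_steady_state(self, abc):
        traj = integrate(abc, ABC_THETA, [0.0, 2000.0])
        assert traj.states[-1] == pytest.approx([0.0, 0.0, 1.0], abs=1e-6)


class TestAbcClosedForm:
    def test_initial_point(self):
        assert abc_closed_form((0.05, 0.1, 1.0), 0.0) == pytest.approx((1.0, 0.0, 0.0))

    def test_values_at_t10(self):
        A, B, C = abc_closed_form(ABC_THETA, 10.0)
        assert float(A) == pytest.approx(0.60653, abs=1e-5)
        assert float(B) == pytest.approx(0.23865, abs=1e-5)
        assert float(C) == pytest.approx(0.15482, abs=1e-5)

    @given(
        th1=st.floats(0.01, 0.2),
        ratio=st.floats(1.1, 8.0),
        th3=st.floats(0.2, 4.0),
        t=st.floats(0.0, 150.0),
    )
    def test_conservation_for_any_parameters(self, th1, ratio, th3, t):
        A, B, C = abc_closed_form((th1, th1 * ratio, th3), t)
        assert float(A + B + C) == pytest.approx(th3, abs=1e-10)

    def test_equal_rates_refused(self):
        with pytest.raises(ValueError, match="theta1 != theta2"):
            abc_closed_form((0.1, 0.1, 1.0), 5.0)

    def test_agrees_with_integrator(self, abc):
        times = np.linspace(0.0, 100.0, 21)
        traj = integrate(abc, ABC_THETA, times)
        A, B, C = abc_closed_form(ABC_THETA, times)
        assert np.max(np.abs(traj.states - np.column_stack([A, B, C]))) < 1e-6


class TestMapkFixture:
    def test_fourteen_free_parameters(self):
        assert mapk_model().n_params == 14

    def test_default_dataset_size(self):
        m = mapk_model()
        data = simulate_dataset(
            m, m.default_theta, mapk_design(), NoiseSpec(sigma=dict(m.noise_sd), seed=0)
        )
        assert len(data) == 33  # 3 observables x 11 times

    def test_moiety_conservation(self):
        m = mapk_model()
        traj = integrate(m, m.default_theta, np.linspace(0.0, 1000.0, 30))
        erk_total = traj.column("Erk") + traj.column("Erk_p") + traj.column("Erk_pp")
        mek_total = traj.column("Mek") + traj.column("Mek_p") + traj.column("Mek_pp")
        assert np.ptp(erk_total) < 1e-5
        assert np.ptp(mek_total) < 1e-5

    def test_trajectories_bounded_nonnegative_over_parameter_box(self):
        m = mapk_model()
        rng = np.random.default_rng(123)
        theta0 = np.asarray(m.default_theta)
        times = np.linspace(0.0, 1000.0, 12)
        total = 100.0 + 300.0 + 300.0
        for _ in range(100):
            theta = theta0 * np.exp(rng.uniform(-1.0, 1.0, size=theta0.size))
            traj = integrate(m, theta, times)
            assert np.all(traj.states > -1e-6)
            assert np.all(traj.states < total)


class TestSimulateDataset:
    def test_zero_sigma_gives_noise_free_observables(self, abc):
        data = simulate_dataset(
            abc, ABC_THETA, abc_full_design(), NoiseSpec(sigma={"C_obs": 0.0}, seed=4)
        )
        _, _, C = abc_closed_form(ABC_THETA, np.asarray(abc_full_design().times))
        assert data.records["value"].to_numpy() == pytest.approx(np.asarray(C, float), abs=1e-7)

    def test_same_seed_byte_identical_csv(self, abc):
        bufs = []
        for _ in range(2):
            data = simulate_dataset(
                abc, ABC_THETA, abc_full_design(),
                NoiseSpec(sigma={"C_obs": 0.1}, seed=99),
            )
            buf = io.StringIO()
            data.records.to_csv(buf, index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_abc_default_record_layout(self, abc_full_data):
        assert len(abc_full_data) == 11
        assert set(abc_full_data.records["observable"]) == {"C_obs"}
        assert abc_full_data.records["sigma"].to_numpy() == pytest.approx(0.1)

    def test_standardized_residuals_white(self, abc):
        designs = [abc_full_design()] * 10
        resid = []
        for seed, design in enumerate(designs):
            data = simulate_dataset(
                abc, ABC_THETA, design, NoiseSpec(sigma={"C_obs": 0.1}, seed=seed)
            )
            _, _, C = abc_closed_form(ABC_THETA, np.asarray(design.times))
            r = (data.records["value"].to_numpy() - np.asarray(C, float)) / 0.1
            resid.append(r)
        r = np.concatenate(resid)
        n = r.size
        assert abs(r.mean()) < 4 / math.sqrt(n)
        assert abs(r.var() - 1.0) < 4 * math.sqrt(2.0 / n)


class TestLinearOracle:
    def test_degenerate_prediction_at_origin(self):
        orc = linear_oracle((1.0, 2.0, 3.0), sigma=1.0, theta_true=1.0, alpha=0.9, t0=0.0)
        assert orc.se_prediction == 0.0
        assert orc.pci_half_width == 0.0

    def test_sd_zero_collapses_vci_to_pci(self):
        orc = linear_oracle((1.0, 2.0), sigma=0.5, theta_true=1.0, alpha=0.9, SD=0.0, t0=2.0)
        assert orc.vci_half_width == pytest.approx(orc.pci_half_width)

    def test_halfwidth_closed_form_value(self):
        orc = linear_oracle(
            tuple(float(t) for t in range(1, 11)), sigma=1.0, theta_true=1.0,
            alpha=0.9, t0=5.0,
        )
        expected = math.sqrt(2.70554) * 5.0 / math.sqrt(385.0)
        assert orc.pci_half_width == pytest.approx(expected, abs=1e-5)

    def test_estimator_is_weighted_least_squares(self):
        times = (1.0, 2.0, 3.0, 4.0)
        orc = linear_oracle(times, sigma=1.0, theta_true=2.0, alpha=0.9)
        y = np.array([2.1, 3.9, 6.2, 7.8])
        manual = float(np.dot(times, y) / np.sum(np.square(times)))
        assert orc.theta_hat(y) == pytest.approx(manual)

    def test_linear_model_runs_through_ode_machinery(self):
        m = linear_model(sigma=1.0)
        traj = integrate(m, [2.0], [0.0, 1.0, 4.0])
        assert traj.column("x") == pytest.approx([0.0, 2.0, 8.0], abs=1e-8)
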