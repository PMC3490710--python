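"""Study models, analytic oracles and the seeded synthetic-data generator.

Two models drive all examples and tests:

* a linear two-step conversion chain A -> B -> C (rates 0.05 and 0.1,
  A(0) = 1 free, B(0) = C(0) = 0 fixed) observed through C with Gaussian
  noise sigma = 0.1 — roughly a 10% signal-to-noise ratio, typical of
  cell-biology time courses; and
* an eight-state MAP kinase cascade (Raf, Raf*, Mek, Mek*, Mek**, Erk, Erk*,
  Erk**) with Michaelis-Menten kinetics and negative feedback of Erk** on Raf
  activation, observed through the phosphorylated sums (Raf*, Mek*+Mek**,
  Erk*+Erk**) with sigma = 10 nM — the phospho-antibody readout of a western
  blot.

The chain model has a closed-form solution used as an integration oracle, and
a purely linear regression model (y = theta * t) provides fully analytic
estimator, profile-curvature and interval formulas for exactness tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .estimation import Dataset
from .model_core import (
    ExperimentalDesign,
    IntegrationError,
    ModelDefinition,
    integrate,
    observe,
)

__all__ = [
    "NoiseSpec",
    "abc_model",
    "abc_closed_form",
    "abc_full_design",
    "abc_short_design",
    "mapk_model",
    "mapk_design",
    "simulate_dataset",
    "linear_model",
    "linear_oracle",
    "LinearOracle",
]

ABC_THETA = np.array([0.05, 0.1, 1.0])
ABC_SIGMA = 0.1
MAPK_SIGMA = 10.0  # nM


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian measurement noise, per observable, seeded."""

    sigma: Mapping[str, float]
    seed: int

    def __post_init__(self):
        for obs, sd in self.sigma.items():
            if not sd >= 0:
                raise ValueError(f"sigma for {obs!r} must be >= 0, got {sd}")


def abc_model() -> ModelDefinition:
    """The two-step conversion chain A -> B -> C.

    Free parameters: the two rates theta1, theta2 and the initial amount
    A(0) = theta3.  B(0) and C(0) are fixed at zero; C is the measured
    observable with sigma = 0.1.
    """
    return ModelDefinition(
        state_names=["A", "B", "C"],
        param_names=["theta1", "theta2", "theta3"],
        rhs={
            "A": "-theta1 * A",
            "B": "theta1 * A - theta2 * B",
            "C": "theta2 * B",
        },
        observation_map={"C_obs": "C"},
        initial_values={"A": "theta3", "B": 0.0, "C": 0.0},
        noise_sd={"C_obs": ABC_SIGMA},
        default_theta=ABC_THETA,
        name="abc_chain",
    )


def abc_full_design() -> ExperimentalDesign:
    """C measured at t = 0, 10, ..., 100: resolves the steady state of C."""
    return ExperimentalDesign(
        times=tuple(float(t) for t in range(0, 101, 10)), observables=("C_obs",)
    )


def abc_short_design() -> ExperimentalDesign:
    """C measured at t = 0, 2, ..., 20: samples only the transient rise of C,
    leaving the concentration scale practically non-identifiable."""
    return ExperimentalDesign(
        times=tuple(float(t) for t in range(0, 21, 2)), observables=("C_obs",)
    )


def abc_closed_form(theta: Sequence[float], t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic solution of the chain: independent oracle for the integrator.

    A(t) = theta3 e^{-theta1 t},
    B(t) = theta3 theta1/(theta2-theta1) (e^{-theta1 t} - e^{-theta2 t}),
    C(t) = theta3 - A - B.
    """
    th1, th2, th3 = (float(v) for v in theta)
    if math.isclose(th1, th2, rel_tol=1e-12, abs_tol=0.0):
        raise ValueError("closed form requires theta1 != theta2")
    t = np.asarray(t, dtype=float)
    A = th3 * np.exp(-th1 * t)
    B = th3 * th1 / (th2 - th1) * (np.exp(-th1 * t) - np.exp(-th2 * t))
    C = th3 - A - B
    return A, B, C


# -- MAP kinase cascade ----------------------------------------------------

# Published parameterization of the oscillatory Michaelis-Menten MAPK cascade
# with negative feedback of doubly phosphorylated Erk on Raf activation.
# Consecutive (de)phosphorylation steps of Mek and Erk share parameters, and
# initial concentrations are fixed (known), leaving 14 free parameters.
_MAPK_PARAMS = {
    "V1": 2.5,   # nM/s, Raf activation Vmax (feedback-inhibited)
    "n": 1.0,    # feedback Hill exponent
    "KI": 9.0,   # nM, feedback inhibition constant
    "K1": 10.0,  # nM
    "V2": 0.25,  # nM/s, Raf* deactivation
    "K2": 8.0,
    "k3": 0.025,  # 1/s, Mek (de)phosphorylation catalytic rates (shared k3=k4)
    "K3": 15.0,   # nM (shared K3=K4)
    "V5": 0.75,   # nM/s, Mek dephosphatase (shared V5=V6)
    "K5": 15.0,   # (shared K5=K6)
    "k7": 0.025,  # 1/s, Erk (de)phosphorylation (shared k7=k8)
    "K7": 15.0,   # (shared K7=K8)
    "V9": 0.5,    # nM/s, Erk phosphatase (shared V9=V10)
    "K9": 15.0,   # (shared K9=K10)
}

_MAPK_INITIALS = {
    "Raf": 90.0, "Raf_p": 10.0,
    "Mek": 280.0, "Mek_p": 10.0, "Mek_pp": 10.0,
    "Erk": 280.0, "Erk_p": 10.0, "Erk_pp": 10.0,
}


def mapk_model() -> ModelDefinition:
    """Eight-state MAP kinase cascade with Erk**-mediated negative feedback.

    Michaelis-Menten rate laws throughout; Raf activation is inhibited by
    Erk** through a Hill term.  Observables are the phosphorylated sums
    Raf*, Mek*+Mek**, Erk*+Erk** with sigma = 10 nM.  Initial concentrations
    are fixed; the 14 rate-law parameters are free.
    """
    v1 = "V1 * Raf / ((1 + (Erk_pp / KI)**n) * (K1 + Raf))"
    v2 = "V2 * Raf_p / (K2 + Raf_p)"
    v3 = "k3 * Raf_p * Mek / (K3 + Mek)"
    v4 = "k3 * Raf_p * Mek_p / (K3 + Mek_p)"
    v5 = "V5 * Mek_pp / (K5 + Mek_pp)"
    v6 = "V5 * Mek_p / (K5 + Mek_p)"
    v7 = "k7 * Mek_pp * Erk / (K7 + Erk)"
    v8 = "k7 * Mek_pp * Erk_p / (K7 + Erk_p)"
    v9 = "V9 * Erk_pp / (K9 + Erk_pp)"
    v10 = "V9 * Erk_p / (K9 + Erk_p)"
    params = list(_MAPK_PARAMS)
    return ModelDefinition(
        state_names=list(_MAPK_INITIALS),
        param_names=params,
        rhs={
            "Raf": f"-({v1}) + ({v2})",
            "Raf_p": f"({v1}) - ({v2})",
            "Mek": f"-({v3}) + ({v6})",
            "Mek_p": f"({v3}) - ({v4}) + ({v5}) - ({v6})",
            "Mek_pp": f"({v4}) - ({v5})",
            "Erk": f"-({v7}) + ({v10})",
            "Erk_p": f"({v7}) - ({v8}) + ({v9}) - ({v10})",
            "Erk_pp": f"({v8}) - ({v9})",
        },
        observation_map={
            "Raf_p_obs": "Raf_p",
            "Mek_phospho": "Mek_p + Mek_pp",
            "Erk_phospho": "Erk_p + Erk_pp",
        },
        initial_values=dict(_MAPK_INITIALS),
        noise_sd={
            "Raf_p_obs": MAPK_SIGMA,
            "Mek_phospho": MAPK_SIGMA,
            "Erk_phospho": MAPK_SIGMA,
        },
        default_theta=[_MAPK_PARAMS[p] for p in params],
        name="mapk_cascade",
        # concentrations are O(100) nM: the absolute floor can sit well above
        # the package default without affecting the objective at threshold scale
        rtol=1e-7,
        atol=1e-7,
    )


def mapk_design() -> ExperimentalDesign:
    """Phospho-sums measured at t = 0, 100, ..., 1000 s."""
    return ExperimentalDesign(
        times=tuple(float(t) for t in range(0, 1001, 100)),
        observables=("Raf_p_obs", "Mek_phospho", "Erk_phospho"),
    )


# -- data generation -------------------------------------------------------


def simulate_dataset(
    model: ModelDefinition,
    theta: Sequence[float],
    design: ExperimentalDesign,
    noise: NoiseSpec,
) -> Dataset:
    """Simulate one noisy dataset y = g(x(t), theta) + eps under a design.

    Identical seeds give identical datasets.  Noise draws are made in a fixed
    (observable-major) order so the stream is independent of dict ordering.
    """
    theta = np.asarray(theta, dtype=float)
    times = np.asarray(design.times, dtype=float)
    sim_times = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    traj = integrate(model, theta, sim_times, input_id=design.input_id)
    keep = np.isin(traj.times, times)
    clean = observe(model, traj, theta, design.observables)[keep]

    rng = np.random.default_rng(noise.seed)
    rows = []
    for j, obs in enumerate(design.observables):
        sd = float(noise.sigma.get(obs, model.noise_sd.get(obs, 0.0)))
        eps = rng.normal(0.0, sd, size=times.size) if sd > 0 else np.zeros(times.size)
        for i, t in enumerate(times):
            rows.append(
                {
                    "time": float(t),
                    "observable": obs,
                    "value": float(clean[i, j] + eps[i]),
                    "sigma": float(sd) if sd > 0 else 1.0,
                }
            )
    return Dataset(records=pd.DataFrame(rows), design=design)


# -- linear-Gaussian analytic oracle --------------------------------------


def linear_model(sigma: float = 1.0) -> ModelDefinition:
    """The one-parameter regression y = theta * t as a state-space model
    (state x with xdot = theta, x(0) = 0), making the fully analytic case
    runnable through the same machinery as the ODE examples."""
    return ModelDefinition(
        state_names=["x"],
        param_names=["theta"],
        rhs={"x": "theta"},
        observation_map={"y": "x"},
        initial_values={"x": 0.0},
        noise_sd={"y": float(sigma)},
        default_theta=[1.0],
        name="linear",
    )


@dataclass(frozen=True)
class LinearOracle:
    """Closed-form reference quantities for the linear-Gaussian model."""

    times: tuple[float, ...]
    sigma: float
    theta_true: float
    alpha: float
    t0: float
    SD: float | None

    @property
    def sum_t2(self) -> float:
        return float(np.sum(np.square(self.times)))

    def theta_hat(self, y: Sequence[float]) -> float:
        """Weighted least-squares estimator sum(t_i y_i) / sum(t_i^2)."""
        t = np.asarray(self.times, dtype=float)
        return float(np.dot(t, np.asarray(y, dtype=float)) / self.sum_t2)

    @property
    def se_theta(self) -> float:
        return self.sigma / math.sqrt(self.sum_t2)

    @property
    def se_prediction(self) -> float:
        """Standard error of the prediction theta * t0."""
        return self.sigma * abs(self.t0) / math.sqrt(self.sum_t2)

    @property
    def pci_half_width(self) -> float:
        return math.sqrt(chi2.ppf(self.alpha, df=1)) * self.se_prediction

    @property
    def vci_half_width(self) -> float:
        sd = 0.0 if self.SD is None else float(self.SD)
        return math.sqrt(chi2.ppf(self.alpha, df=1)) * math.sqrt(
            self.se_prediction**2 + sd**2
        )

    def profile_curvature_prediction(self) -> float:
        """Curvature of -2 PPL in z: 1 / se^2."""
        return 1.0 / self.se_prediction**2

    def profile_curvature_validation(self) -> float:
        """Curvature of -2 VPL in z: 1 / (se^2 + SD^2)."""
        sd = 0.0 if self.SD is None else float(self.SD)
        return 1.0 / (self.se_prediction**2 + sd**2)


def linear_oracle(
    times: Sequence[float],
    sigma: float,
    theta_true: float,
    alpha: float,
    SD: float | None = None,
    t0: float | None = None,
) -> LinearOracle:
    """Analytic estimator law, profile curvatures and PCI/VCI half-widths for
    the regression y = theta * t with known noise sigma."""
    times = tuple(float(t) for t in times)
    if not np.sum(np.square(times)) > 0:
        raise ValueError("need sum(t_i^2) > 0")
    return LinearOracle(
        times=times,
        sigma=float(sigma),
        theta_true=float(theta_true),
        alpha=float(alpha),
        t0=float(times[-1] if t0 is None else t0),
        SD=SD,
    )
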