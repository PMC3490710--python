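"""Shared fixtures: models, seeded datasets and fits reused across tests.

Everything is generated programmatically; session scope keeps the expensive
multi-start fits to one per model/design combination.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from predprofile import (
    ExperimentalDesign,
    NoiseSpec,
    abc_full_design,
    abc_model,
    abc_short_design,
    fit,
    linear_model,
    linear_oracle,
    simulate_dataset,
)
from predprofile.fixtures import ABC_THETA

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

LINEAR_TIMES = tuple(float(t) for t in range(1, 11))
LINEAR_SIGMA = 1.0
LINEAR_T0 = 5.0


@pytest.fixture(scope="session")
def abc():
    return abc_model()


@pytest.fixture(scope="session")
def abc_full_data(abc):
    noise = NoiseSpec(sigma={"C_obs": 0.1}, seed=42)
    return simulate_dataset(abc, ABC_THETA, abc_full_design(), noise)


@pytest.fixture(scope="session")
def abc_full_fit(abc, abc_full_data):
    return fit(abc, abc_full_data, n_starts=5, seed=1)


@pytest.fixture(scope="session")
def abc_short_data(abc):
    noise = NoiseSpec(sigma={"C_obs": 0.1}, seed=11)
    return simulate_dataset(abc, ABC_THETA, abc_short_design(), noise)


@pytest.fixture(scope="session")
def abc_short_fit(abc, abc_short_data):
    return fit(abc, abc_short_data, n_starts=5, seed=1)


@pytest.fixture(scope="session")
def linear():
    return linear_model(sigma=LINEAR_SIGMA)


@pytest.fixture(scope="session")
def linear_design():
    return ExperimentalDesign(times=LINEAR_TIMES, observables=("y",))


@pytest.fixture(scope="session")
def linear_data(linear, linear_design):
    noise = NoiseSpec(sigma={"y": LINEAR_SIGMA}, seed=7)
    return simulate_dataset(linear, [1.0], linear_design, noise)


@pytest.fixture(scope="session")
def linear_fit(linear, linear_data):
    return fit(linear, linear_data, n_starts=3, seed=1)


@pytest.fixture(scope="session")
def linear_ref():
    """Closed-form oracle quantities for the shared linear setup."""
    return linear_oracle(
        LINEAR_TIMES, sigma=LINEAR_SIGMA, theta_true=1.0, alpha=0.9, SD=0.3,
        t0=LINEAR_T0,
    )
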