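import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isens

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fast_sim_config() -> isens.SimulationConfig:
    """A small cohort configuration; the reduced calibration Monte Carlo is
    fine for rank-identity checks, which do not depend on the calibration
    accuracy."""
    return isens.SimulationConfig(
        n_subjects=400, seed=11, calibration_mc_size=5_000,
        calibration_tolerance=0.05,
    )


@pytest.fixture(scope="session")
def fast_cohort(fast_sim_config) -> isens.SimulatedCohort:
    return isens.simulate_cohort(fast_sim_config)


@pytest.fixture(scope="session")
def default_cohort_10k() -> isens.SimulatedCohort:
    """One cohort at the study's headline conditions (defaults, n=10,000),
    shared across tests to keep the calibration Monte Carlo a one-off."""
    return isens.simulate_cohort(isens.SimulationConfig(n_subjects=10_000, seed=1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180626 % 2**31)
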