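import numpy as np
import pytest

from hdrisk.classify import RFConfig
from hdrisk.cohort import CohortConfig, PatientProfile, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The 200-session default cohort, shared across tests (seed 7)."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_symptomatic(default_cohort):
    return [s for s in default_cohort if s.symptomatic]


@pytest.fixture
def small_config():
    """A 4-patient, 8-session mini cohort config for fast end-to-end tests."""
    profiles = [
        PatientProfile("a", 60, "M", 2, 75.0, 3.0, 120.0, 8.0, 70.0, 5.0, 70.0, 4.0),
        PatientProfile("b", 55, "F", 2, 65.0, 2.5, 130.0, 7.0, 75.0, 4.0, 65.0, 4.0),
        PatientProfile("c", 70, "M", 1, 85.0, 3.5, 115.0, 9.0, 65.0, 5.0, 72.0, 4.5),
        PatientProfile("d", 48, "F", 0, 58.0, 2.8, 125.0, 6.0, 78.0, 4.5, 68.0, 3.5),
    ]
    return CohortConfig(profiles=profiles, sessions_per_patient=8, seed=11)


@pytest.fixture
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def fast_rf():
    return RFConfig(n_trees=25, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
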