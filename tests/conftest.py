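import numpy as np
import pytest

from interopipe import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant cohort with no missingness, shared across tests."""
    return simulate_cohort(CohortConfig(n_participants=60, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
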