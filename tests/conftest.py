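import numpy as np
import pytest

import strokesofa as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A reproducible 250-patient synthetic cohort shared across tests."""
    return ss.generate_cohort(ss.CohortSpec(n_patients=250, seed=3))
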