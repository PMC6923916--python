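import numpy as np
import pytest

from ssnet import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """One cohort at the reference configuration, shared across tests."""
    return simulate_cohort(SyntheticConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
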