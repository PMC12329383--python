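import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

from scedlab import SimulationConfig, simulate_dataset
from scedlab import datasets


@pytest.fixture(scope="session")
def study_dataset():
    """The reference assessment dataset (11 parents, T0/T1/T2 scores)."""
    return datasets.assessment_dataset()


@pytest.fixture(scope="session")
def simulated_dataset():
    """One deterministic synthetic study, reused across read-only tests."""
    return simulate_dataset(SimulationConfig(), seed=20240917)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
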