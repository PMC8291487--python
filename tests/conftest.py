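import numpy as np
import pytest
from hypothesis import settings

from evokit.demography import DemographicModel, SampleConfig

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def const_model():
    """Single constant-size population, the classic neutral baseline."""
    return DemographicModel(populations=[("A", 1.0)])


@pytest.fixture(scope="session")
def sample20():
    return SampleConfig(entries=[("A", 20, 0.0)])


@pytest.fixture(scope="session")
def neutral_reps(const_model, sample20):
    """The calibration run: n=20, theta=5, 2000 neutral replicates."""
    from evokit.coalescent import run_replicates

    return run_replicates(const_model, sample20, theta=5.0, n_reps=2000, seed=101)
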