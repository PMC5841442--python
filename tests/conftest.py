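import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isonicheweb import default_scenario, generate_dataset, noise_free_scenario

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def dataset(scenario):
    return generate_dataset(scenario, seed=101)


@pytest.fixture(scope="session")
def nf_scenario():
    return noise_free_scenario()


@pytest.fixture(scope="session")
def nf_dataset(nf_scenario):
    return generate_dataset(nf_scenario, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
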