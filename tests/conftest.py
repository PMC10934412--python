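import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polyuptake.synth import SynthParams, simulate_library

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams(seed=1)


@pytest.fixture(scope="session")
def noiseless_params() -> SynthParams:
    return SynthParams(seed=1).noiseless()


@pytest.fixture(scope="session")
def default_library(default_params):
    """One default synthetic library (48 members, 3 loads, both cell lines)."""
    return simulate_library(default_params)


@pytest.fixture(scope="session")
def noiseless_library(noiseless_params):
    return simulate_library(noiseless_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240220)
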