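import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from memconsol import ParameterSet, equilibrate
from memconsol.protocols import run_training

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def std_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def std_basal(std_params) -> np.ndarray:
    return equilibrate(std_params)


@pytest.fixture(scope="session")
def training_run(std_params):
    """One standard 9-day training trajectory, shared across tests."""
    return run_training(std_params, horizon_days=9.0)
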