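import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radkin import FOParams, SimulationConfig, SOParams, simulate_trace

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def so_truth() -> SOParams:
    """Well-identified second-order ground truth used across tests."""
    return SOParams(k=0.01, ar0=1.0, aah0=1.5)


@pytest.fixture(scope="session")
def noiseless_so_trace(so_truth):
    return simulate_trace(
        SimulationConfig("SO", so_truth, noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def fo2_truth() -> FOParams:
    return FOParams(amplitudes=(0.5, 0.4), time_constants=(50.0, 500.0), y0=0.2)


@pytest.fixture(scope="session")
def noiseless_fo2_trace(fo2_truth):
    return simulate_trace(
        SimulationConfig("FO2", fo2_truth, noise_sigma=0.0)
    )


@pytest.fixture()
def grid() -> np.ndarray:
    return np.arange(0.0, 1001.0)
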