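import numpy as np
import pytest

from vitiphen.synthetic_data import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def clean_collection():
    """Small clean (uncorrupted) collection shared across tests."""
    return simulate_dataset(30, (0.4, 0.3, 0.3), SimulationParams.clean(), seed=123)


@pytest.fixture(scope="session")
def corrupted_collection():
    """Collection with default contamination and gaps."""
    params = SimulationParams(cloud_rate=0.05, heavy_rate=0.0)
    return simulate_dataset(60, (0.4, 0.3, 0.3), params, seed=321)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
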