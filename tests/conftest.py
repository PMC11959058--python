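import numpy as np
import pytest

from sweatkin import ModelParameters, SimulationGrid, default_parameters


@pytest.fixture(scope="session")
def defaults() -> ModelParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def coarse_grid() -> SimulationGrid:
    """Cheap grid for tests that run many forward solves."""
    return SimulationGrid(n_isf=16, n_sg=64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
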