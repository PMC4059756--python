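import numpy as np
import pytest

from dscaif import SimulationConfig, TimeGrid, build_dataset, make_true_aif


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def true_aif(grid):
    return make_true_aif(grid)


@pytest.fixture(scope="session")
def default_dataset():
    """Full default population (1902 voxels, SNR 20), seed 1."""
    return build_dataset(SimulationConfig(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
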