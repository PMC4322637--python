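import numpy as np
import pytest

from stimdense.grids import VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture
def unit_grid():
    """10^3 grid of 1 mm cells with origin at the world origin."""
    return VoxelGrid((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (10, 10, 10))


@pytest.fixture
def straight_streamline():
    """30 mm straight polyline along x, 0.1 mm vertex spacing."""
    from stimdense.streamlines import Streamline

    x = np.linspace(0.0, 30.0, 301)
    return Streamline(np.column_stack([x, np.zeros_like(x), np.zeros_like(x)]))


@pytest.fixture(scope="session")
def membrane_params():
    from stimdense.axon import load_membrane_parameters

    return load_membrane_parameters()


@pytest.fixture(scope="session")
def straight_axon(membrane_params):
    """Cable model on a straight 30 mm fiber (61 nodes), reused across tests."""
    from stimdense.axon import build_axon
    from stimdense.streamlines import Streamline

    x = np.linspace(0.0, 30.0, 301)
    s = Streamline(np.column_stack([x, np.zeros_like(x), np.zeros_like(x)]))
    return build_axon(s, params=membrane_params)
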