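import numpy as np
import pytest

from tetherwalk import LatticeGeometry, LatticeState, map_preset


@pytest.fixture
def geometry():
    return LatticeGeometry()


@pytest.fixture
def small_geometry():
    return LatticeGeometry(n_protofilaments=5, n_sites=20)


@pytest.fixture
def empty_state(geometry):
    return LatticeState.empty(geometry)


@pytest.fixture
def fl_map7():
    return map_preset("FL_MAP7")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
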