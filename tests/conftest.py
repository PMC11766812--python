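import numpy as np
import pytest

from magbead import magnetics as mag
from magbead import materials as mat
from magbead import transport as trans


@pytest.fixture(scope="session")
def assembly():
    return mag.ApplicatorAssembly()


@pytest.fixture(scope="session")
def magnet():
    """Single default block, face-centre field anchor ~120 kA/m."""
    return mag.CuboidMagnet()


@pytest.fixture(scope="session")
def wire():
    return mat.default_microwire()


@pytest.fixture(scope="session")
def bead():
    return mat.default_bead()


@pytest.fixture(scope="session")
def channel():
    return trans.ChannelGeometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
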