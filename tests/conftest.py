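import numpy as np
import pytest

from restgraph import GroundTruth, make_geometry


@pytest.fixture(scope="session")
def geom_small():
    """Compact lattice for fast unit tests: 100 voxels, 8 regions."""
    return make_geometry((5, 5, 4), 8, seed=0)


@pytest.fixture(scope="session")
def geom_study():
    """Study-scale lattice: ~200 gray voxels, 10 regions."""
    return make_geometry((7, 7, 6), 10, seed=0)


@pytest.fixture()
def truth_default():
    return GroundTruth(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, n, p=0.3):
    """Symmetric simple random graph as a dense 0/1 matrix."""
    a = (rng.random((n, n)) < p).astype(np.int64)
    a = np.triu(a, k=1)
    return a + a.T
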