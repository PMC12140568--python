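import numpy as np
import pytest

from remnantnet.network import WeightedNetwork
from remnantnet.parcellation import Parcellation
from remnantnet.synthetic import make_suite


def random_symmetric(n, rng, positive=True, kind="FC", signed=None):
    """Random symmetric zero-diagonal weight matrix."""
    w = rng.random((n, n)) if positive else rng.standard_normal((n, n))
    w = np.triu(w, 1)
    w = w + w.T
    if signed is None:
        signed = not positive
    return WeightedNetwork(w, kind=kind, signed=signed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_net(rng):
    return random_symmetric(8, rng)


@pytest.fixture
def parcels_toy():
    rng = np.random.default_rng(7)
    half = 5
    right = np.column_stack(
        [rng.uniform(5, 60, half), rng.uniform(-80, 80, half), rng.uniform(-50, 50, half)]
    )
    left = right * np.array([-1.0, 1.0, 1.0])
    return Parcellation(
        region_id=tuple(f"L{i}" for i in range(half))
        + tuple(f"R{i}" for i in range(half)),
        hemisphere=("L",) * half + ("R",) * half,
        centroid=np.vstack([left, right]),
        volume=np.full(2 * half, 1000.0),
    )


@pytest.fixture(scope="session")
def suite60():
    """A shared desk-scale synthetic suite (n=60, T=200)."""
    return make_suite(n=60, T_timepoints=200, seed=202)
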