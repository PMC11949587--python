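import numpy as np
import pytest

from hopfnet import (
    RegionAtlas,
    SimulationSettings,
    make_connectome,
    make_natural_frequencies,
)
from hopfnet.spectral import PLIMatrix


@pytest.fixture(scope="session")
def conn6():
    """Small dense connected connectome for fast end-to-end tests."""
    return make_connectome(6, density=0.8, seed=3)


@pytest.fixture(scope="session")
def omega6():
    return make_natural_frequencies(6, seed=3)


@pytest.fixture(scope="session")
def fast_settings():
    """Short simulations at a reduced sampling rate for unit tests."""
    return SimulationSettings(duration_s=4.0, burn_in_s=1.0, fs_hz=250.0)


@pytest.fixture(scope="session")
def atlas_with_centroids():
    rng = np.random.default_rng(11)
    labels = tuple(f"roi_{i:02d}" for i in range(12))
    return RegionAtlas(labels=labels, centroids=rng.normal(size=(12, 3)))


def random_pli(n, seed, labels=None, source="empirical"):
    """Random valid PLI matrix (symmetric, zero diagonal, entries in [0,1])."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.0, 1.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    if labels is None:
        labels = tuple(f"roi_{i:02d}" for i in range(n))
    return PLIMatrix(values=v, labels=labels, source=source)
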