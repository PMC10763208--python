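import numpy as np
import pytest

from leaflayers import (
    GAConfig,
    LayerPartition,
    LeafBiochem,
    default_grid,
    make_synthetic_constants,
)


@pytest.fixture(scope="session")
def constants():
    return make_synthetic_constants(seed=0)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def biochem():
    return LeafBiochem(N=1.0, cab=30.0, cw=0.02, cm=0.006)


@pytest.fixture
def partition():
    return LayerPartition(N1=2.003, N2=0.4, cab12=0.9, cm12=0.85)


@pytest.fixture
def fast_ga():
    """Small optimizer budget for smoke tests."""
    return GAConfig(pop_size=20, generations=10, seed=0)


def random_layer(rng):
    """A random physically valid symmetric layer (R + T <= 1)."""
    r = rng.uniform(0.0, 0.6)
    t = rng.uniform(0.0, 1.0 - r - 1e-3)
    from leaflayers import LayerOptics

    return LayerOptics(r, t, r, t)
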