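import numpy as np
import pytest

from emva.map_io import DensityMap


@pytest.fixture
def rng():
    return np.random.default_rng(20130921)


@pytest.fixture
def random_map(rng):
    """A small anisotropic random map with a non-trivial origin."""
    return DensityMap(
        rng.normal(size=(6, 8, 10)).astype(np.float32),
        voxel_size=(1.0, 1.5, 2.0),
        origin=(-3.0, 2.0, 7.5),
    )


@pytest.fixture
def constant_map():
    return DensityMap(np.full((4, 4, 4), 2.5), voxel_size=(1.0, 1.0, 1.0))
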