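import numpy as np
import pytest

from rimsift import BinaryMask, PhantomSpec, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A small, quick-to-generate phantom subject."""
    return PhantomSpec(grid_shape=(48, 48, 48), n_nprwml=10, n_prl=6,
                       n_enhancing=2, n_tiny=2,
                       lesion_radius_range_mm=(1.0, 2.0), seed=7)


@pytest.fixture
def random_volume(rng):
    data = rng.normal(50, 20, (8, 8, 8))
    return Volume(data, np.diag([0.5, 0.5, 0.5, 1.0]))


def make_mask(data, voxel=0.5):
    return BinaryMask(np.asarray(data, dtype=np.uint8),
                      np.diag([voxel, voxel, voxel, 1.0]))
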