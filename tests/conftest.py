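import numpy as np
import pytest

from morphoct.phantoms import PhantomSpec, SceneSpec, make_scene
from morphoct.volume_io import BinaryVolume, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flat_slab_spec():
    return PhantomSpec("twisted_slab", length=60, width=30, thickness=5, twist=0.0)


@pytest.fixture(scope="session")
def twisted_slab_spec():
    return PhantomSpec("twisted_slab", length=60, width=30, thickness=5, twist=180.0)


@pytest.fixture(scope="session")
def flat_scene(flat_slab_spec):
    """Default phantom scene (noise sd 5, seed 1) plus ground truth."""
    return make_scene(SceneSpec(plant=flat_slab_spec, noise_sd=5.0, seed=1))


@pytest.fixture(scope="session")
def twisted_scene(twisted_slab_spec):
    return make_scene(SceneSpec(plant=twisted_slab_spec, noise_sd=5.0, seed=1))


def jaccard(a: BinaryVolume, b: BinaryVolume) -> float:
    inter = (a.data & b.data).sum()
    union = (a.data | b.data).sum()
    return inter / union


@pytest.fixture
def two_cubes():
    """27-voxel and 8-voxel cubes, well separated."""
    grid = np.zeros((10, 10, 10), dtype=bool)
    grid[1:4, 1:4, 1:4] = True
    grid[6:8, 6:8, 6:8] = True
    return BinaryVolume(grid)
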