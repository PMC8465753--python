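import numpy as np
import pytest

from glioprofile.synthetic import default_geometry, generate_bundle
from glioprofile.volumes import BinaryMask, VolumeGeometry


@pytest.fixture(scope="session")
def geometry():
    return default_geometry((48, 48, 48))


@pytest.fixture(scope="session")
def bundle(geometry):
    return generate_bundle(geometry, seed=7)


@pytest.fixture
def small_geometry():
    return VolumeGeometry.isotropic((12, 12, 12))


def random_mask(geometry, rng, density=0.15, smooth=True):
    """A random but spatially coherent non-empty mask for oracle comparisons."""
    data = rng.random(geometry.shape) < density
    if smooth:
        from scipy import ndimage
        data = ndimage.binary_dilation(data)
    if not data.any():
        data[tuple(s // 2 for s in geometry.shape)] = True
    return BinaryMask(geometry, data)


def cube_mask(geometry, corner, size):
    data = np.zeros(geometry.shape, dtype=bool)
    sl = tuple(slice(c, c + size) for c in corner)
    data[sl] = True
    return BinaryMask(geometry, data)
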