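import numpy as np
import pytest

from halovasc import BinaryVolume, GreyStack
from halovasc.phantoms import rasterize_tube


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def hollow_square_tube():
    """Axis-aligned hollow square tube: outer 5x5, wall 1 voxel, open along z."""
    v = np.zeros((20, 12, 12), dtype=bool)
    v[:, 4:9, 4:9] = True
    v[:, 5:8, 5:8] = False
    return BinaryVolume(v)


@pytest.fixture
def solid_cylinder():
    """Solid digital cylinder, radius 3 px, length 40, along z."""
    return BinaryVolume(rasterize_tube((40, 15, 15), (0, 7, 7), (39, 7, 7), 3))


@pytest.fixture
def torus():
    """Solid torus (one loop): tube radius 3 around a radius-7 circle."""
    z, y, x = np.mgrid[-5:6, -12:13, -12:13]
    return BinaryVolume((np.sqrt(x**2 + y**2) - 7) ** 2 + z**2 <= 3**2)


@pytest.fixture
def bimodal_stack(rng):
    """Noisy two-population stack: dark background, bright sparse signal."""
    vals = np.where(
        rng.random((12, 40, 40)) < 0.08,
        rng.normal(190, 15, (12, 40, 40)),
        rng.normal(25, 6, (12, 40, 40)),
    )
    return GreyStack(np.clip(np.rint(vals), 0, 255).astype(np.uint8), 0.54, 0.54)
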