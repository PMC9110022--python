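import numpy as np
import pytest

from hsfuse.cube_io import HyperspectralCube, RgbImage, default_wavelengths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """4x4x5 random transmittance cube."""
    return HyperspectralCube(rng.uniform(0.1, 1.0, (4, 4, 5)),
                             default_wavelengths(5))


@pytest.fixture
def textured_image(rng):
    """A 256x256 RGB image with enough texture for feature detection."""
    base = rng.uniform(0, 1, (32, 32))
    img = np.kron(base, np.ones((8, 8)))
    img = img + 0.1 * rng.standard_normal(img.shape)
    img = (img - img.min()) / (img.max() - img.min())
    rgb = np.stack([img, np.roll(img, 3, axis=0), img ** 2], axis=2)
    return RgbImage(np.clip(rgb, 0, 1))
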