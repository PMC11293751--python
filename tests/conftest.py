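import numpy as np
import pytest

from tumorseg.core_io import GrayImage
from tumorseg.synthetic import make_phantom, random_phantom_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_image():
    """1000-pixel linear ramp on [0, 1] reshaped to 2-D."""
    vals = np.linspace(0.0, 1.0, 1000)
    return GrayImage(pixels=vals.reshape(25, 40))


@pytest.fixture
def abnormal_phantom():
    rng = np.random.default_rng(7)
    spec = random_phantom_spec(rng, 1, min_radius=20, max_radius=25)
    return make_phantom(spec)


def downsample(img: GrayImage, factor: int = 4) -> GrayImage:
    """Block-mean downsampling used to shrink phantoms for classifier tests."""
    p = img.pixels
    h, w = p.shape
    return GrayImage(
        p.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))
    )
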