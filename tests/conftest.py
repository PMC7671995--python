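import numpy as np
import pytest

from polypaug.sample import ImageSample
from polypaug.synthetic import SyntheticConfig, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def endo_sample():
    """A 64x64 synthetic frame with void border and a mid-size polyp."""
    cfg = SyntheticConfig(
        height=64, width=64, void_fraction=0.15, polyp_area_fraction=0.12, seed=42
    )
    return generate_sample(cfg)


@pytest.fixture
def tiny_sample(rng):
    """An 8x8 random frame with a small square polyp, for oracle tests."""
    image = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[2:4, 3:6] = 1
    void = np.zeros((8, 8), dtype=np.uint8)
    void[0, 0] = 1
    image[0, 0] = 0
    return ImageSample(image=image, mask=mask, void_mask=void, id="tiny")
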