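import numpy as np
import pytest

from rfilm.dataio import BinaryMask, FieldImage
from rfilm.model import ModelConfig, build_modified_unet

TINY_CFG = ModelConfig(encoder_channels=(4, 8, 12), bottleneck_channels=16)


@pytest.fixture
def tiny_model():
    """A very small (randomly initialised) modified U-Net for fast tests."""
    return build_modified_unet(TINY_CFG, rng=0)


def random_pair(rng: np.random.Generator, h: int = 32, w: int = 32, weather: str = "cloudy",
                height_m: float = 5.0, film_prob: float = 0.1) -> tuple[FieldImage, BinaryMask]:
    """A random image with a random (unrelated) binary mask."""
    img = FieldImage(
        rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8),
        weather=weather,
        height_m=height_m,
    )
    mask = BinaryMask((rng.random((h, w)) < film_prob).astype(np.uint8))
    return img, mask
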