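import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from steatoscan.patches import Patch
from steatoscan.synth import SpeckleParams, UltrasoundImage, generate_image


@pytest.fixture
def flat_image():
    """A deterministic 64x64 gradient image with a full-frame ROI."""
    pixels = (np.arange(64 * 64).reshape(64, 64) % 251).astype(np.uint8)
    return UltrasoundImage(pixels=pixels, class_label="C1", roi=(0, 0, 64, 64),
                           image_id="grad_0")


@pytest.fixture
def speckle_image():
    params = SpeckleParams(class_label="C3", target_mean=150.0, seed=7)
    return generate_image(params, 96, 96)


def constant_patch(value: float, label: str, w: int = 4, idx: int = 0) -> Patch:
    """A w x w patch of a single gray value, for hand-checkable arithmetic."""
    return Patch(
        pixels=np.full((w, w), value, dtype=np.float64),
        class_label=label,
        image_id=f"const_{label}_{idx}",
        origin=(idx, 0),
    )
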