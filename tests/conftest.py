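import numpy as np
import pytest
from hypothesis import settings

from embryoquant.core import BinaryMask

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_disk_mask(radius: float, pixel_size: float = 1.0, pad: int = 8) -> BinaryMask:
    size = int(2 * radius) + 2 * pad + 1
    rr, cc = np.mgrid[0:size, 0:size]
    center = size // 2
    return BinaryMask((rr - center) ** 2 + (cc - center) ** 2 <= radius**2, pixel_size)


def make_rect_mask(
    rows: int, cols: int, pixel_size: float = 1.0, pad: int = 6
) -> BinaryMask:
    return BinaryMask(np.pad(np.ones((rows, cols), dtype=bool), pad), pixel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
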