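import numpy as np
import pytest

from lyticgray import ImageGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20140625)


@pytest.fixture
def random_grid_12bit(rng):
    """A 40x50 grid of uniform 12-bit gray levels (ROI-sized)."""
    return ImageGrid(pixels=rng.integers(0, 4096, size=(50, 40)).astype(np.uint16))
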