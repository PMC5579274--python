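import numpy as np
import pytest

from radrisk.image_core import ImageVolume, QuantizedROI, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_quantized_roi(rng, shape=(3, 3, 3), n_gray=4, p_roi=0.8) -> QuantizedROI:
    """Random quantized ROI: each voxel in-ROI with prob p_roi, levels uniform."""
    while True:
        mask = rng.random(shape) < p_roi
        if mask.any():
            break
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_gray + 1, size=int(mask.sum()))
    return QuantizedROI(levels, n_gray)


def line_roi(values, n_gray) -> QuantizedROI:
    """A 1 x len x 1 ROI with the given levels."""
    arr = np.asarray(values, dtype=np.int64).reshape(1, -1, 1)
    return QuantizedROI(arr, n_gray)


@pytest.fixture
def ramp_volume():
    """Linear ramp f(x,y,z) = x (in mm) on a 1 mm grid with a full mask."""
    shape = (8, 6, 6)
    data = np.broadcast_to(
        np.arange(shape[0], dtype=float)[:, None, None], shape
    ).copy()
    vol = ImageVolume(data, (1.0, 1.0, 1.0))
    mask = ROIMask(np.ones(shape, dtype=bool), (1.0, 1.0, 1.0))
    return vol, mask
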