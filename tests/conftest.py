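import numpy as np
import pytest

from msunet.volume_io import CHANNEL_ORDER, LesionMask, MultimodalVolume, \
    VolumeGrid


@pytest.fixture
def trial_grid():
    """Small grid at the clinical-trial resolution (3 mm slices)."""
    return VolumeGrid((8, 24, 24), (3.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(grid, rng, lesion_mask=None, shift=30.0):
    """Simple multimodal volume: base + noise, lesions shifted on all
    channels."""
    channels = {}
    for i, name in enumerate(CHANNEL_ORDER):
        data = 100.0 + 10.0 * rng.standard_normal(grid.shape) + 5.0 * i
        if lesion_mask is not None:
            data = data + shift * lesion_mask
        channels[name] = data.astype(np.float32)
    return MultimodalVolume(grid, channels)


@pytest.fixture
def blob_mask(trial_grid):
    """One 3x3x3 (27-voxel) lesion blob."""
    m = np.zeros(trial_grid.shape, dtype=np.uint8)
    m[3:6, 10:13, 10:13] = 1
    return LesionMask(trial_grid, m)
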