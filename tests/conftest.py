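import numpy as np
import pytest
from scipy import ndimage

from trabtex.preprocess import BinaryROI


def random_blobs(side: int, seed: int, fraction: float = 0.5, scale: float = 3.0) -> BinaryROI:
    """Smooth-noise blob image with roughly the requested white fraction."""
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((side, side)), scale)
    t = np.quantile(field, 1.0 - fraction)
    return BinaryROI(phase=field >= t, pixel_spacing=1.0)


@pytest.fixture
def blob_roi():
    return random_blobs(64, seed=42)
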