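import numpy as np
import pytest

from tomoaccess import SegmentationMask
from tomoaccess.phantoms import make_random_blobs


@pytest.fixture
def blob_mask():
    """One fixed irregular 16^3 mask with a lumen-like slab seed."""
    mask, _ = make_random_blobs((16, 16, 16), 1.0, porosity=0.5,
                                rng_seed=42, lumen_depth=3)
    return mask


@pytest.fixture
def ball_mask():
    """Solid biomass ball of radius 20 voxels, spacing 1 nm."""
    z, y, x = np.indices((46, 46, 46), dtype=float)
    ball = (z - 23) ** 2 + (y - 23) ** 2 + (x - 23) ** 2 <= 20.0 ** 2
    return SegmentationMask(np.where(ball, 1, 0).astype(np.int8), 1.0)


def brute_force_edt(mask: SegmentationMask) -> np.ndarray:
    """O(n^2) pairwise-minimum oracle for the EDT."""
    from scipy.spatial.distance import cdist

    pts = np.indices(mask.shape).reshape(3, -1).T * mask.spacing
    bio = np.argwhere(mask.biomass) * mask.spacing
    d = cdist(pts, bio).min(axis=1)
    return d.reshape(mask.shape)
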