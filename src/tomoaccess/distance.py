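"""Euclidean distance transform of a segmentation and its void thresholds.

The EDT assigns to every voxel the exact Euclidean distance (nm, between
voxel centers) to the nearest biomass voxel; it is the radius of the largest
spherical probe centered at that voxel that avoids biomass.  Thresholding it
at radius ``r`` gives ``Void(r)``, the locus of feasible centers for a
radius-``r`` probe, whose connected components are the regions such a probe
can explore without crossing a bottleneck.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume_io import BinaryVolume, ScalarVolume, SegmentationMask

__all__ = ["compute_edt", "threshold_void", "connected_components",
           "connectivity_structure"]


def connectivity_structure(connectivity: int = 6) -> np.ndarray:
    """3x3x3 structuring element for 6-, 18- or 26-connectivity."""
    rank = {6: 1, 18: 2, 26: 3}
    try:
        return ndimage.generate_binary_structure(3, rank[connectivity])
    except KeyError:
        raise ValueError(
            f"connectivity must be 6, 18 or 26, got {connectivity}") from None


def compute_edt(mask: SegmentationMask) -> ScalarVolume:
    """Exact Euclidean distance transform to the nearest biomass voxel.

    Lumen voxels count as void.  The grid boundary is open: edge voxels
    measure distance only to biomass inside the grid, so boundary void can
    act as a probe source.  Distances are between voxel centers, in nm.
    """
    if not mask.biomass.any():
        raise ValueError("EDT undefined: empty biomass")
    # distance_transform_edt measures to the nearest zero => zero out biomass
    edt = ndimage.distance_transform_edt(
        mask.void, sampling=(mask.spacing,) * 3)
    return ScalarVolume(edt, mask.spacing, mask.origin, role="edt")


def threshold_void(edt: ScalarVolume, r: float) -> BinaryVolume:
    """``Void(r)``: voxels with EDT strictly greater than ``r`` (nm).

    ``Void(0)`` is exactly the void space; the strict inequality means
    ``Void(max EDT)`` is empty.
    """
    if r < 0:
        raise ValueError(f"radius must be nonnegative, got {r}")
    if edt.role not in ("edt", "aedt"):
        raise ValueError(f"threshold_void expects an EDT-like volume, "
                         f"got role={edt.role!r}")
    return BinaryVolume(edt.values > r, edt.spacing, edt.origin)


def connected_components(binary: BinaryVolume,
                         connectivity: int = 6) -> tuple[np.ndarray, int]:
    """Label connected components of a binary volume.

    Returns ``(labels, count)`` with components numbered 1..count and 0 as
    background.  The default 6-connectivity is the physically conservative
    choice for probe motion: a sphere of positive radius cannot pass
    through an edge- or corner-only voxel contact.
    """
    labels, count = ndimage.label(
        binary.values, structure=connectivity_structure(connectivity))
    return labels, int(count)
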