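"""Biomass surface extraction, per-vertex accessibility, and area curves.

The biomass surface is triangulated by marching cubes on the binary
biomass indicator at iso-level 0.5.  Each vertex is then assigned an
accessibility value: the maximum aCRT over voxel centers within a range
of interaction ε of the vertex.  The ε-ball maximum exists because the
aCRT is discontinuous at the biomass surface (zero inside, possibly large
just outside); sampling voxel centers within ε — rather than
interpolating — picks the void-side value a catalyst within chemical
reach would see.  ε defaults to 1.1 voxel widths (about 2.2 nm on a
~2 nm tomogram grid): just over one voxel, enough to counteract partial
volume effects without inflating the measured areas.

The accessible-area curve integrates, for each probe radius r, the area
of surface whose accessibility is at least r.  A triangle counts as
accessible when all three of its vertices pass (conservative lower-area
rule; a mean-vertex rule is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .volume_io import ScalarVolume, SegmentationMask

__all__ = ["SurfaceMesh", "AccessibilityCurve", "extract_surface",
           "sample_surface_accessibility", "accessible_area_curve",
           "biomass_stats"]


@dataclass
class SurfaceMesh:
    """Triangulated biomass surface in physical (nm) coordinates."""

    vertices: np.ndarray                 # (V, 3) nm, (z, y, x) order
    triangles: np.ndarray                # (F, 3) vertex indices
    accessibility: np.ndarray | None = None   # (V,) nm, set after sampling
    iso_level: float = 0.5
    provenance: str = ""

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def total_area(self) -> float:
        """Total surface area, nm^2."""
        return float(self.triangle_areas().sum())


@dataclass
class AccessibilityCurve:
    """Accessible surface area versus probe radius, with normalizations."""

    radii: np.ndarray                    # nm, ascending
    area: np.ndarray                     # nm^2
    frac_total_area: np.ndarray          # area / total mesh area
    area_per_biomass_vol: np.ndarray     # 1/um: area / biomass volume
    seed_strategy: str = ""

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.area = np.asarray(self.area, dtype=float)


def extract_surface(mask: SegmentationMask,
                    smooth_sigma: float = 0.5) -> SurfaceMesh:
    """Marching-cubes triangulation of the biomass surface.

    The biomass indicator is lightly Gaussian-smoothed (``smooth_sigma``
    voxels, default 0.5) before running marching cubes at iso-level 0.5:
    on raw binary data the staircase triangulation overestimates curved
    areas by ~8%, while the smoothed indicator keeps sphere and box areas
    within a few percent of their analytic values and moves vertices by
    under half a voxel.  If smoothing leaves no iso-crossing (a feature
    thinner than the kernel, e.g. a single-voxel grain), the binary field
    is used unsmoothed so the surface is never lost.  Vertices come out
    in physical nm ((z, y, x) order, offset by the grid origin).
    Interfaces cut by the domain boundary are left open: artificial cut
    faces are not biomass surface.
    """
    bio = mask.biomass
    if not bio.any():
        raise ValueError("mask contains no biomass: no surface to extract")
    if bio.all():
        raise ValueError("mask is entirely biomass: no surface to extract")
    s = mask.spacing
    field = bio.astype(np.float32)
    if smooth_sigma > 0:
        from scipy import ndimage

        smoothed = ndimage.gaussian_filter(field, smooth_sigma)
        if smoothed.max() > 0.5 and smoothed.min() < 0.5:
            field = smoothed
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=(s, s, s))
    verts = verts + np.asarray(mask.origin, dtype=float)
    return SurfaceMesh(verts, faces.astype(np.int64),
                       provenance=f"marching_cubes level=0.5 spacing={s} "
                                  f"smooth_sigma={smooth_sigma}")


def sample_surface_accessibility(mesh: SurfaceMesh, acrt: ScalarVolume,
                                 epsilon: float | None = None) -> np.ndarray:
    """Per-vertex accessibility: max aCRT over voxel centers within ε (nm).

    ``epsilon`` defaults to 1.1 voxel widths and must be positive; voxel
    centers are sampled directly (no interpolation).  The result is also
    stored on ``mesh.accessibility``.
    """
    s = acrt.spacing
    if epsilon is None:
        epsilon = 1.1 * s
    if epsilon <= 0:
        raise ValueError(f"range of interaction must be positive, got {epsilon}")
    vals = np.asarray(acrt.values, dtype=float)
    shape = np.array(vals.shape)
    origin = np.asarray(acrt.origin, dtype=float)
    verts = np.asarray(mesh.vertices, dtype=float)
    lo = (verts - origin).min(axis=0)
    hi = (verts - origin).max(axis=0)
    if lo.min() < -s or np.any(hi > (shape - 1) * s + s):
        raise ValueError("mesh does not lie within the aCRT grid")

    rv = int(np.ceil(epsilon / s))
    off = np.indices((2 * rv + 1,) * 3).reshape(3, -1).T - rv
    out = np.empty(len(verts), dtype=float)
    chunk = max(1, 2_000_000 // max(1, len(off)))
    for start in range(0, len(verts), chunk):
        v = verts[start:start + chunk]
        base = np.rint((v - origin) / s).astype(np.intp)
        cand = base[:, None, :] + off[None, :, :]           # (c, K, 3)
        centers = cand * s + origin
        d2 = ((centers - v[:, None, :]) ** 2).sum(axis=2)
        inside = ((cand >= 0) & (cand < shape)).all(axis=2)
        ok = inside & (d2 <= epsilon ** 2 * (1 + 1e-12))
        cand_clipped = np.clip(cand, 0, shape - 1)
        sampled = vals[cand_clipped[..., 0], cand_clipped[..., 1],
                       cand_clipped[..., 2]]
        sampled[~ok] = -np.inf
        out[start:start + chunk] = sampled.max(axis=1)
    out[~np.isfinite(out)] = 0.0
    mesh.accessibility = out
    return out


def accessible_area_curve(mesh: SurfaceMesh, vertex_values: np.ndarray,
                          radii=None, rule: str = "all",
                          mask: SegmentationMask | None = None,
                          seed_strategy: str = "") -> AccessibilityCurve:
    """Accessible surface area as a function of probe radius.

    ``radii=None`` uses 0 plus every distinct positive vertex value — the
    exact step curve.  ``rule`` is ``all`` (a triangle counts when all
    three vertices have accessibility >= r; conservative) or ``mean``.
    The per-volume normalization (1/µm) needs ``mask`` for the biomass
    volume and is NaN otherwise.
    """
    vv = np.asarray(vertex_values, dtype=float)
    areas = mesh.triangle_areas()
    if rule == "all":
        tri_stat = vv[mesh.triangles].min(axis=1)
    elif rule == "mean":
        tri_stat = vv[mesh.triangles].mean(axis=1)
    else:
        raise ValueError(f"unknown triangle rule {rule!r}")
    if radii is None:
        radii = np.r_[0.0, np.unique(vv[vv > 0])]
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("empty radius list")
    if np.any(np.diff(radii) < 0) or radii.min() < 0:
        raise ValueError("radii must be sorted ascending and nonnegative")

    order = np.argsort(tri_stat, kind="stable")
    sorted_stat = tri_stat[order]
    # cumulative area of triangles with stat >= r, via suffix sums
    suffix = np.r_[np.cumsum(areas[order][::-1])[::-1], 0.0]
    idx = np.searchsorted(sorted_stat, radii, side="left")
    area = suffix[idx]

    total = float(areas.sum())
    frac = area / total if total > 0 else np.full_like(area, np.nan)
    if mask is not None:
        vol_nm3 = float(mask.biomass.sum()) * mask.spacing ** 3
        per_vol = area / vol_nm3 * 1e3  # nm^-1 -> um^-1
    else:
        per_vol = np.full_like(area, np.nan)
    return AccessibilityCurve(radii, area, frac, per_vol, seed_strategy)


def biomass_stats(mask: SegmentationMask, mesh: SurfaceMesh) -> dict:
    """Biomass volume (µm³), surface area (µm²) and their ratio (µm⁻¹)."""
    vol_um3 = float(mask.biomass.sum()) * mask.spacing ** 3 * 1e-9
    area_um2 = mesh.total_area() * 1e-6
    return {"biomass_volume_um3": vol_um3,
            "surface_area_um2": area_um2,
            "area_per_volume_per_um": area_um2 / vol_um3 if vol_um3 else np.inf}
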