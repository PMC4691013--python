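"""Synthetic segmentations with analytically known accessibility structure.

Each generator rasterizes an analytic solid by a voxel-center inclusion
test onto the ``(z, y, x)`` grid and returns a
:class:`~tomoaccess.volume_io.SegmentationMask` together with a plain
ground-truth record (cavity radii, bottleneck radii, gap widths) that
downstream tests consume.  Radii recovered from the rasterized phantoms
are accurate to about one voxel, the discretization error of
center-sampled rasterization.

Geometries emulate the situations that matter for cell-wall
accessibility: an isolated spherical pore (covering-radius semantics), a
dumbbell of two cavities joined by a narrow channel (a bottleneck), a
slab with internal delaminations reachable from the section boundary but
not the lumen, a corrugated "rough" lumenal wall (surface-texture-driven
accessibility decay, no cavities at all), and smoothed-noise blobs for
oracle-equivalence stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .volume_io import BIOMASS, LUMEN, VOID, SegmentationMask

__all__ = ["PhantomSpec", "generate", "make_sphere_pore", "make_dumbbell",
           "make_delaminated_slab", "make_rough_wall", "make_random_blobs",
           "write_ground_truth", "read_ground_truth"]


@dataclass
class PhantomSpec:
    """Recipe for a reproducible phantom: geometry name + parameters."""

    geometry: str
    shape: tuple[int, int, int]
    spacing: float = 1.0
    params: dict = dc_field(default_factory=dict)
    rng_seed: int = 0


_GENERATORS = {}


def generate(spec: PhantomSpec):
    """Dispatch a :class:`PhantomSpec` to its generator.

    Returns ``(mask, ground_truth_dict)``.
    """
    try:
        fn = _GENERATORS[spec.geometry]
    except KeyError:
        raise ValueError(f"unknown phantom geometry {spec.geometry!r}; "
                         f"known: {sorted(_GENERATORS)}") from None
    kwargs = dict(spec.params)
    if spec.geometry in ("rough_wall", "random_blobs"):
        kwargs.setdefault("rng_seed", spec.rng_seed)
    return fn(spec.shape, spec.spacing, **kwargs)


def _register(fn):
    _GENERATORS[fn.__name__.removeprefix("make_")] = fn
    return fn


def _grids(shape, spacing):
    z, y, x = np.indices(shape, dtype=float)
    return z * spacing, y * spacing, x * spacing


def _physical_extent(shape, spacing):
    return tuple((n - 1) * spacing for n in shape)


@_register
def make_sphere_pore(shape, spacing, R: float, open_to_boundary: bool = False,
                     channel_radius: float | None = None):
    """Solid biomass block containing a spherical void pore of radius R (nm).

    Optionally opened to the axial (z-) boundary face through a cylindrical
    channel (default radius: R, i.e. no bottleneck).  Ground truth: CRT = R
    throughout the pore; EDT at the pore center = R.
    """
    if R < 2 * spacing:
        raise ValueError(f"pore radius {R} must be >= 2 voxels ({2 * spacing})")
    ext = _physical_extent(shape, spacing)
    # center on a voxel center so recovered radii are sharp
    center = (np.array(shape) // 2) * spacing
    if np.any(np.minimum(center, ext - center) - R < spacing) \
            and not open_to_boundary:
        raise ValueError("sphere does not fit the grid with a biomass margin")
    z, y, x = _grids(shape, spacing)
    d2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    void = d2 <= R ** 2
    if open_to_boundary:
        cr = R if channel_radius is None else channel_radius
        rad2 = (y - center[1]) ** 2 + (x - center[2]) ** 2
        void |= (rad2 <= cr ** 2) & (z <= center[0])
    labels = np.where(void, VOID, BIOMASS).astype(np.int8)
    truth = {"R_nm": R, "center_voxel": tuple(np.round(center / spacing).astype(int)),
             "open_to_boundary": open_to_boundary,
             "channel_radius_nm": (R if channel_radius is None else channel_radius)
             if open_to_boundary else None}
    return SegmentationMask(labels, spacing), truth


@_register
def make_dumbbell(shape, spacing, R1: float, R2: float, a: float,
                  open_side: str = "none", open_radius: float | None = None,
                  lumen: bool = False):
    """Two spherical cavities joined by a cylindrical channel of radius a.

    The dumbbell axis runs along x; cavity 1 (radius R1) sits at low x,
    cavity 2 (radius R2) at high x.  ``a`` is the bottleneck radius (nm);
    ``a = 0`` leaves the cavities disconnected.  ``open_side`` in
    {left, right, both, none} adds cylindrical openings of radius
    ``open_radius`` (default: the adjacent cavity radius) to the x- / x+
    boundary.  With ``lumen=True`` the opening void within 2 voxels of the
    open face is labeled LUMEN, modelling a lumen sliver at the mouth.
    """
    if a >= min(R1, R2) and a > 0:
        raise ValueError(f"channel radius a={a} must be < min(R1, R2)")
    if open_side not in ("left", "right", "both", "none"):
        raise ValueError(f"bad open_side {open_side!r}")
    ext = _physical_extent(shape, spacing)
    margin = 2 * spacing
    # centers on voxel centers so recovered radii are sharp
    cz = (shape[0] // 2) * spacing
    cy = (shape[1] // 2) * spacing
    c1x = round((margin + R1 + spacing) / spacing) * spacing
    c2x = round((ext[2] - margin - R2 - spacing) / spacing) * spacing
    if c2x - c1x < R1 + R2 + 2 * spacing:
        raise ValueError("dumbbell does not fit the grid along x")
    if max(R1, R2) + margin > min(cz, cy):
        raise ValueError("dumbbell cavities do not fit the grid cross-section")
    z, y, x = _grids(shape, spacing)
    void = ((z - cz) ** 2 + (y - cy) ** 2 + (x - c1x) ** 2 <= R1 ** 2) \
        | ((z - cz) ** 2 + (y - cy) ** 2 + (x - c2x) ** 2 <= R2 ** 2)
    rad2 = (z - cz) ** 2 + (y - cy) ** 2
    if a > 0:
        void |= (rad2 <= a ** 2) & (x >= c1x) & (x <= c2x)
    open_left = open_side in ("left", "both")
    open_right = open_side in ("right", "both")
    if open_left:
        r = R1 if open_radius is None else open_radius
        void |= (rad2 <= r ** 2) & (x <= c1x)
    if open_right:
        r = R2 if open_radius is None else open_radius
        void |= (rad2 <= r ** 2) & (x >= c2x)
    labels = np.where(void, VOID, BIOMASS).astype(np.int8)
    if lumen:
        if open_left:
            labels[:, :, :2][labels[:, :, :2] == VOID] = LUMEN
        if open_right:
            labels[:, :, -2:][labels[:, :, -2:] == VOID] = LUMEN
        if not (open_left or open_right):
            raise ValueError("lumen=True requires an open side")
    truth = {"R1_nm": R1, "R2_nm": R2, "bottleneck_nm": a,
             "center1_voxel": (int(round(cz / spacing)), int(round(cy / spacing)),
                               int(round(c1x / spacing))),
             "center2_voxel": (int(round(cz / spacing)), int(round(cy / spacing)),
                               int(round(c2x / spacing))),
             "open_side": open_side}
    return SegmentationMask(labels, spacing), truth


@_register
def make_delaminated_slab(shape, spacing, n_gaps: int = 2,
                          gap_half_widths=(2.0,), connect_to_lumen: bool = False,
                          neck_radius: float | None = None,
                          lumen_frac: float = 0.2):
    """Biomass slab with planar delamination gaps, lumen on both sides.

    The slab is normal to y; the void on either side is labeled LUMEN.
    Gaps are planar voids parallel to the slab faces spanning the full z
    and x extent, so they touch the axial (z) boundary faces but not the
    lumen — reproducing delaminations reachable by boundary seeding yet
    lumen-inaccessible.  ``connect_to_lumen=True`` drills a cylindrical
    neck (radius ``neck_radius`` nm, along y) from each gap to the nearer
    lumen, making the gap lumen-accessible through that bottleneck.
    """
    gap_half_widths = list(gap_half_widths)
    if len(gap_half_widths) == 1:
        gap_half_widths = gap_half_widths * n_gaps
    if len(gap_half_widths) != n_gaps:
        raise ValueError("need one gap half-width, or one per gap")
    ext = _physical_extent(shape, spacing)
    y_lo, y_hi = lumen_frac * ext[1], (1 - lumen_frac) * ext[1]
    z, y, x = _grids(shape, spacing)
    labels = np.full(shape, BIOMASS, dtype=np.int8)
    labels[y < y_lo] = LUMEN
    labels[y > y_hi] = LUMEN

    gap_ys = np.linspace(y_lo, y_hi, n_gaps + 2)[1:-1]
    slab_thick = (y_hi - y_lo) / (n_gaps + 1)
    for gy, w in zip(gap_ys, gap_half_widths):
        if 2 * w >= slab_thick - 2 * spacing:
            raise ValueError(f"gap half-width {w} too large for slab spacing")
        labels[np.abs(y - gy) <= w] = VOID
    if connect_to_lumen:
        if neck_radius is None:
            raise ValueError("connect_to_lumen=True requires neck_radius")
        for i, (gy, w) in enumerate(zip(gap_ys, gap_half_widths)):
            # stagger neck positions across gaps
            ncz = ext[0] * (0.3 + 0.4 * (i % 2))
            ncx = ext[2] * (0.3 + 0.4 * ((i // 2) % 2))
            toward_lo = gy - y_lo <= y_hi - gy
            span = (y >= y_lo - spacing) & (y <= gy) if toward_lo \
                else (y >= gy) & (y <= y_hi + spacing)
            neck = ((z - ncz) ** 2 + (x - ncx) ** 2 <= neck_radius ** 2) & span
            labels[neck & (labels == BIOMASS)] = VOID
    truth = {"n_gaps": n_gaps, "gap_half_widths_nm": tuple(gap_half_widths),
             "connect_to_lumen": connect_to_lumen,
             "neck_radius_nm": neck_radius}
    return SegmentationMask(labels, spacing), truth


@_register
def make_rough_wall(shape, spacing, amplitude: float = 0.0,
                    wavelength: float = 20.0, rng_seed: int = 0,
                    lumen_frac: float = 0.15):
    """Corrugated biomass wall below an open lumen: texture, no cavities.

    Biomass occupies ``y < h(x)`` with ``h(x) = H0 + amplitude *
    cos(2*pi*x/wavelength + phase)`` — corrugation along x only, constant
    along z, so the void is a height field with no bottlenecks and every
    seeding strategy yields identical accessibility.  ``amplitude = 0``
    gives a flat wall.  The top ``lumen_frac`` of the grid is labeled
    LUMEN.  The random phase comes from ``rng_seed``.
    """
    ext = _physical_extent(shape, spacing)
    h0 = 0.35 * ext[1]
    if amplitude < 0 or (amplitude > 0 and h0 - amplitude < spacing):
        raise ValueError("amplitude must be >= 0 and leave a biomass base")
    rng = np.random.default_rng(rng_seed)
    phase = rng.uniform(0, 2 * np.pi)
    z, y, x = _grids(shape, spacing)
    h = h0 + amplitude * np.cos(2 * np.pi * x / wavelength + phase)
    labels = np.where(y < h, BIOMASS, VOID).astype(np.int8)
    labels[y > (1 - lumen_frac) * ext[1]] = LUMEN
    truth = {"amplitude_nm": amplitude, "wavelength_nm": wavelength,
             "base_height_nm": h0, "phase_rad": phase}
    return SegmentationMask(labels, spacing), truth


@_register
def make_random_blobs(shape, spacing, porosity: float = 0.5,
                      kernel_width: float = 2.0, rng_seed: int = 0,
                      lumen_depth: int = 0):
    """Irregular biomass from thresholded smoothed Gaussian noise.

    ``porosity`` sets the void voxel fraction; ``kernel_width`` is the
    Gaussian smoothing sigma in voxels (feature scale).  With
    ``lumen_depth > 0`` the void voxels in the first ``lumen_depth``
    y-slices are labeled LUMEN (a lumen-like slab seed for accessibility
    stress tests).
    """
    if not 0 < porosity < 1:
        raise ValueError(f"porosity must be in (0, 1), got {porosity}")
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=kernel_width)
    cutoff = np.quantile(smooth, 1.0 - porosity)
    labels = np.where(smooth < cutoff, BIOMASS, VOID).astype(np.int8)
    if labels.min() == labels.max():  # degenerate draw; keep both phases
        labels.flat[0] = VOID if labels.flat[0] == BIOMASS else BIOMASS
    if lumen_depth > 0:
        sl = labels[:, :lumen_depth, :]
        sl[sl == VOID] = LUMEN
    truth = {"porosity": porosity, "kernel_width_vox": kernel_width,
             "rng_seed": rng_seed}
    return SegmentationMask(labels, spacing), truth


# ---------------------------------------------------------------------------
# ground-truth sidecars
# ---------------------------------------------------------------------------

def write_ground_truth(path: str, record: dict) -> None:
    """Write a ground-truth record as plain ``key = value`` text."""
    with open(path, "w") as fh:
        for k, v in record.items():
            fh.write(f"{k} = {v!r}\n")


def read_ground_truth(path: str) -> dict:
    import ast

    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            out[k.strip()] = ast.literal_eval(v.strip())
    return out
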