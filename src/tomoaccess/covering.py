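"""Covering-radius-type transforms by maximal-sphere painting.

Given a nonnegative distance field ``D`` (an EDT or an accessible EDT),
every voxel ``x`` defines a sphere of radius ``D(x)`` centered there — the
largest probe that can sit at ``x``.  Painting each sphere with its radius
and keeping the pointwise maximum yields the covering radius transform
(local thickness): ``CRT(y) = max{D(x) : |y - x| <= D(x)}``, the largest
probe that can *overlap* ``y``.  Applied to an accessible EDT the same
painting produces the accessible CRT, which labels whole cavities with the
radius of the bottleneck guarding them.
"""

from __future__ import annotations

import numpy as np

from .volume_io import ScalarVolume

__all__ = ["sphere_max_paint", "sphere_max_paint_bruteforce",
           "nonredundant_centers"]

_ROLE_OUT = {"edt": "crt", "aedt": "acrt"}

# centers per painting batch; bounds the temporary index array to
# ~_CHUNK x (ball size) int64 entries
_CHUNK = 2048


def _voxel_coords(shape):
    return np.indices(shape).reshape(3, -1).T


def sphere_max_paint(D: ScalarVolume, centers: np.ndarray | None = None
                     ) -> ScalarVolume:
    """Covering transform of a distance field by maximal-sphere painting.

    At each voxel ``x`` with ``D(x) > 0`` the sphere ``{y : |y - x| <=
    D(x)}`` (physical distance, inclusive, clipped at the grid boundary) is
    painted with value ``D(x)``; the output keeps the pointwise maximum
    over all spheres.  Painting is a pointwise max, so the result is
    independent of visiting order.  Painting only writes where ``D > 0``:
    the maximal sphere's boundary touches the nearest biomass voxel center
    at exactly distance ``D(x)``, and an inclusive test would smear
    positive radii onto biomass, whereas a probe overlaps the points of
    void space it covers, not the wall it rests against.  Biomass and void
    unreachable by any sphere therefore stay 0.

    Parameters
    ----------
    D : ScalarVolume with role ``edt`` or ``aedt``
    centers : (m, 3) int array, optional
        Restrict painting to these centers (used by non-redundant-center
        painting).  Default: all voxels.
    """
    if D.role not in _ROLE_OUT:
        raise ValueError(f"sphere_max_paint expects role edt/aedt, "
                         f"got {D.role!r}")
    vals = np.asarray(D.values, dtype=float)
    if vals.size and vals.min() < 0:
        raise ValueError("distance field contains negative values")
    shape = vals.shape
    spacing = D.spacing
    out = np.zeros(shape, dtype=float)

    if centers is None:
        radii_all = vals
        coords = np.argwhere(radii_all > 0)
    else:
        coords = np.asarray(centers, dtype=np.intp).reshape(-1, 3)
        coords = coords[vals[tuple(coords.T)] > 0]
    if coords.size == 0:
        return ScalarVolume(out, spacing, D.origin, role=_ROLE_OUT[D.role])
    radii = vals[tuple(coords.T)]

    # Process centers in descending-radius groups of equal value: one ball
    # offset stencil per distinct radius, and painted values never need
    # re-checking because later groups are smaller.
    order = np.argsort(-radii, kind="stable")
    coords, radii = coords[order], radii[order]
    group_starts = np.flatnonzero(np.r_[True, radii[1:] != radii[:-1]])
    group_ends = np.r_[group_starts[1:], len(radii)]
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.intp)
    outflat = out.ravel()
    support = vals.ravel() > 0

    for gs, ge in zip(group_starts, group_ends):
        r = radii[gs]
        rv = int(np.floor(r / spacing + 1e-9))
        off = np.indices((2 * rv + 1,) * 3).reshape(3, -1).T - rv
        off = off[np.einsum("ij,ij->i", off, off) * spacing ** 2
                  <= r ** 2 * (1 + 1e-12)]
        cgroup = coords[gs:ge]
        step = max(1, (_CHUNK * 64) // max(64, len(off)))
        for lo in range(0, len(cgroup), step):
            cs = cgroup[lo:lo + step]
            pts = cs[:, None, :] + off[None, :, :]
            ok = ((pts >= 0) & (pts < np.array(shape))).all(axis=2)
            flat = (pts @ strides)[ok]
            if flat.size:
                # all prior paints are >= r, so plain assignment where
                # currently smaller realizes the pointwise max
                flat = flat[support[flat] & (outflat[flat] < r)]
                outflat[np.unique(flat)] = r

    return ScalarVolume(out, spacing, D.origin, role=_ROLE_OUT[D.role])


def sphere_max_paint_bruteforce(D: ScalarVolume) -> ScalarVolume:
    """Literal double-loop painting: for every center, test every voxel.

    Reference implementation of the defining double loop (over centers x
    and grid voxels y, keeping ``max D(x)`` subject to ``|y - x| <=
    D(x)``), quadratic in the voxel count and meant for small test grids.
    """
    if D.role not in _ROLE_OUT:
        raise ValueError(f"expected role edt/aedt, got {D.role!r}")
    vals = np.asarray(D.values, dtype=float)
    shape = vals.shape
    out = np.zeros(shape, dtype=float)
    grid = _voxel_coords(shape) * D.spacing
    flat = out.ravel()
    support = vals.ravel() > 0
    for x in np.argwhere(vals > 0):
        d = vals[tuple(x)]
        dist2 = ((grid - x * D.spacing) ** 2).sum(axis=1)
        hit = (dist2 <= d ** 2 * (1 + 1e-12)) & support
        np.maximum(flat, np.where(hit, d, 0.0), out=flat)
    return ScalarVolume(out, D.spacing, D.origin, role=_ROLE_OUT[D.role])


def nonredundant_centers(D: ScalarVolume) -> np.ndarray:
    """Centers of non-redundant spheres of a distance field.

    A center ``x`` is redundant when some other center ``x'`` satisfies
    ``D(x') >= D(x) + |x - x'|``: its sphere then lies entirely inside the
    sphere of ``x'``, so painting from ``x`` can never raise the output.
    The surviving centers lie along the ridges of ``D``.  Painting from
    the returned (m, 3) voxel set reproduces the full paint exactly.
    """
    vals = np.asarray(D.values, dtype=float)
    coords = np.argwhere(vals > 0)
    if len(coords) == 0:
        return coords
    radii = vals[tuple(coords.T)]
    pos = coords * D.spacing
    keep = np.ones(len(coords), dtype=bool)
    # descending radius: a sphere can only be contained in a strictly larger one
    order = np.argsort(-radii, kind="stable")
    pos_o, radii_o = pos[order], radii[order]
    for i in range(1, len(order)):
        d = np.linalg.norm(pos_o[:i] - pos_o[i], axis=1)
        if np.any(radii_o[:i] >= radii_o[i] + d - 1e-9 * D.spacing):
            keep[order[i]] = False
    return coords[keep]
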