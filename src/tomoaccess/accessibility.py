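"""Seed regions, accessibility tagging, and the accessible EDT / CRT.

The accessible EDT from a seed region Σ is a widest-path (maximum
bottleneck) quantity: ``aEDT(x)`` is the largest probe radius ``r`` for
which a path from Σ to ``x`` stays inside ``Void(r)``.  On the voxel grid
this is the max over discrete paths of the min EDT along the path,
endpoints included.

The production route computes it through the join tree.  Seeding follows
the three-step tagging scheme — select the seed parts of the tree, tag
the descent from seeds toward the roots with the EDT itself, then give
every untagged subtree the value of the branch node attaching it to a
tagged path (the radius of the widest bottleneck leading into it).  It is
implemented as a max-min propagation over the tree graph with per-edge
seed capacity (the best seed EDT on that edge), which reduces to exactly
those three steps when seeds sit at leaves and extends them to arbitrary
voxel seeds such as a thin lumen sliver.  The per-voxel lookup is
``aEDT = min(EDT, tag)``: a probe must both fit at the voxel and pass the
guarding bottleneck.

Two independent oracles implement the definition directly (bottleneck
Dijkstra on the voxel grid, and a descending threshold sweep of flood
fills) and serve as ground truth in tests.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contour_tree import ContourTree
from .covering import sphere_max_paint
from .distance import connectivity_structure
from .volume_io import ScalarVolume, SegmentationMask

__all__ = ["SeedRegion", "TaggedTree", "select_seed", "tag_tree",
           "compute_aedt", "compute_acrt", "aedt_widest_path_oracle",
           "aedt_threshold_sweep_oracle"]


@dataclass
class SeedRegion:
    """Source region Σ of hypothetical diffusing spherical probes.

    ``strategy`` is ``lumen`` (all LUMEN-labeled voxels), ``boundary``
    (void voxels on selected grid faces) or ``none`` (no restriction: the
    accessible transforms reduce to the plain EDT/CRT).  ``voxels`` is an
    (m, 3) int array, empty for ``none``.
    """

    strategy: str
    voxels: np.ndarray
    faces: tuple[str, ...] = ()

    def mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        if len(self.voxels):
            out[tuple(self.voxels.T)] = True
        return out


@dataclass
class TaggedTree:
    """Contour tree plus a per-edge accessibility tag (nm).

    ``tags[e]`` is the widest-bottleneck radius from the seed into edge
    ``e``'s contour class: +inf where the seed governs an entire edge (the
    EDT itself rules there, the seeded-descent sentinel), finite positive
    behind bottlenecks, and 0 on parts unreachable at any positive radius.
    """

    tree: ContourTree
    tags: np.ndarray
    seed: SeedRegion


_FACE_AXIS = {"z-": (0, 0), "z+": (0, -1), "y-": (1, 0), "y+": (1, -1),
              "x-": (2, 0), "x+": (2, -1)}


def select_seed(mask: SegmentationMask, strategy: str = "boundary",
                faces: tuple[str, ...] | None = None) -> SeedRegion:
    """Build a seed region from a named strategy.

    ``lumen`` takes the LUMEN-labeled voxels; ``boundary`` takes the void
    voxels on the chosen grid faces (default: the two faces normal to the
    thinnest grid axis, the axial section boundaries of a tomogram);
    ``none`` means unrestricted accessibility.
    """
    if strategy == "none":
        return SeedRegion("none", np.empty((0, 3), dtype=np.intp))
    if strategy == "lumen":
        vox = np.argwhere(mask.lumen)
        if len(vox) == 0:
            raise ValueError("strategy 'lumen' requires LUMEN labels in the mask")
        return SeedRegion("lumen", vox)
    if strategy == "boundary":
        if faces is None:
            ax = int(np.argmin(mask.shape))
            faces = (("z-", "z+"), ("y-", "y+"), ("x-", "x+"))[ax]
        sel = np.zeros(mask.shape, dtype=bool)
        for f in faces:
            axis, end = _FACE_AXIS[f]
            idx = [slice(None)] * 3
            idx[axis] = end
            sel[tuple(idx)] = True
        vox = np.argwhere(sel & mask.void)
        if len(vox) == 0:
            raise ValueError(f"empty seed: faces {faces} contain no void voxels")
        return SeedRegion("boundary", vox, tuple(faces))
    raise ValueError(f"unknown seed strategy {strategy!r}")


def tag_tree(tree: ContourTree, seed: SeedRegion) -> TaggedTree:
    """Accessibility-tag the contour tree from a seed region.

    Every edge whose contour class contains a seed voxel gets capacity
    equal to the largest seed EDT on it; capacities then propagate across
    tree nodes, each node's EDT value capping what can pass (max-min
    Dijkstra on the tree graph).  An edge whose capacity covers its whole
    level span is reported with the +inf seeded sentinel; edges never
    reached keep tag 0.  Strategy ``none`` seeds everything at +inf.
    """
    n_edges = len(tree.edges)
    if seed.strategy == "none":
        return TaggedTree(tree, np.full(n_edges, np.inf), seed)
    if len(seed.voxels) == 0:
        raise ValueError("empty seed region")
    if tree.edt is None:
        raise ValueError("tree carries no source EDT; rebuild with build_contour_tree")

    edge_of_seed = tree.voxel_map[tuple(seed.voxels.T)]
    if np.any(edge_of_seed < 0):
        raise ValueError("seed voxels must lie in void space")
    seed_vals = np.asarray(tree.edt.values, dtype=float)[tuple(seed.voxels.T)]

    cap = np.full(n_edges, -np.inf)
    np.maximum.at(cap, edge_of_seed, seed_vals)

    node_val = np.array([n.value for n in tree.nodes])
    incident = tree.node_edges()
    # max-min propagation: process edges in decreasing capacity order
    heap = [(-cap[e], e) for e in np.flatnonzero(np.isfinite(cap))]
    heapq.heapify(heap)
    done = np.zeros(n_edges, dtype=bool)
    while heap:
        negc, e = heapq.heappop(heap)
        if done[e]:
            continue
        done[e] = True
        c = -negc
        for node in (tree.edges[e].upper, tree.edges[e].lower):
            through = min(c, node_val[node])
            for e2 in incident[node]:
                if not done[e2] and through > cap[e2]:
                    cap[e2] = through
                    heapq.heappush(heap, (-through, e2))

    tags = np.where(np.isfinite(cap), np.maximum(cap, 0.0), 0.0)
    # seeded-descent sentinel: the capacity covers the edge's whole span,
    # so the EDT alone governs every voxel on it
    upper_vals = node_val[[e.upper for e in tree.edges]]
    tags[tags >= upper_vals] = np.inf
    return TaggedTree(tree, tags, seed)


def compute_aedt(edt: ScalarVolume, tagged: TaggedTree) -> ScalarVolume:
    """Accessible EDT by tag lookup: ``aEDT = min(EDT, tag(edge))``.

    Zero on biomass and on void unreachable from the seed at any positive
    radius; equals the EDT on seeded descents; equals the bottleneck
    radius deep inside guarded cavities.  Always ``<= EDT`` voxelwise.
    """
    if tagged.tree.voxel_map.shape != edt.values.shape:
        raise ValueError("tagged tree and EDT are on different grids")
    vals = np.asarray(edt.values, dtype=float)
    out = np.zeros(vals.shape, dtype=float)
    void = tagged.tree.voxel_map >= 0
    tag_of_voxel = np.zeros(vals.shape, dtype=float)
    tag_of_voxel[void] = tagged.tags[tagged.tree.voxel_map[void]]
    out[void] = np.minimum(vals[void], tag_of_voxel[void])
    return ScalarVolume(out, edt.spacing, edt.origin, role="aedt")


def compute_acrt(aedt: ScalarVolume) -> ScalarVolume:
    """Accessible CRT: maximal-sphere painting of the accessible EDT.

    Labels each cavity interior uniformly with the radius of the widest
    bottleneck leading into it; with an unrestricted seed this is the
    plain CRT.
    """
    return sphere_max_paint(aedt)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def aedt_widest_path_oracle(edt: ScalarVolume, seed: SeedRegion,
                            connectivity: int = 6) -> ScalarVolume:
    """Max-min path aEDT by bottleneck Dijkstra on the voxel grid.

    Directly maximizes, over discrete paths from any seed voxel, the
    minimum EDT along the path (endpoints included).  Exact but O(n log n)
    with Python-level heap traffic — intended for small test grids.
    """
    vals = np.asarray(edt.values, dtype=float)
    shape = vals.shape
    out = np.zeros(shape, dtype=float)
    if seed.strategy == "none":
        out[:] = vals
        return ScalarVolume(out, edt.spacing, edt.origin, role="aedt")

    # pad with a -1 sentinel so neighbor indexing never needs bounds checks
    valsp = np.pad(vals, 1, constant_values=-1.0).ravel()
    bestp = np.zeros_like(valsp)
    pz, py, px = shape[0] + 2, shape[1] + 2, shape[2] + 2
    struct = connectivity_structure(connectivity)
    offs = [int(o[0] * py * px + o[1] * px + o[2])
            for o in (np.argwhere(struct) - 1) if any(o)]
    heap = []
    for v in seed.voxels:
        fi = int((v[0] + 1) * py * px + (v[1] + 1) * px + (v[2] + 1))
        d = valsp[fi]
        if d > bestp[fi]:
            bestp[fi] = d
            heap.append((-d, fi))
    heapq.heapify(heap)
    push, pop = heapq.heappush, heapq.heappop
    while heap:
        negd, fi = pop(heap)
        d = -negd
        if d < bestp[fi]:
            continue
        for off in offs:
            j = fi + off
            w = valsp[j]
            nd = d if w >= d else w
            if nd > bestp[j]:
                bestp[j] = nd
                push(heap, (-nd, j))
    best = bestp.reshape(pz, py, px)[1:-1, 1:-1, 1:-1]
    return ScalarVolume(best, edt.spacing, edt.origin, role="aedt")


def aedt_threshold_sweep_oracle(edt: ScalarVolume, seed: SeedRegion,
                                connectivity: int = 6) -> ScalarVolume:
    """aEDT by sweeping flood fills over descending EDT thresholds.

    For each distinct EDT value v (largest first), label the superlevel
    set {EDT >= v} and assign v to still-unassigned voxels whose component
    contains a seed voxel.  Cross-checks the widest-path oracle.
    """
    vals = np.asarray(edt.values, dtype=float)
    out = np.zeros(vals.shape, dtype=float)
    if seed.strategy == "none":
        out[:] = vals
        return ScalarVolume(out, edt.spacing, edt.origin, role="aedt")
    seed_mask = seed.mask(vals.shape)
    struct = connectivity_structure(connectivity)
    assigned = np.zeros(vals.shape, dtype=bool)
    for v in np.unique(vals[vals > 0])[::-1]:
        labels, _ = ndimage.label(vals >= v, structure=struct)
        hit = np.unique(labels[seed_mask & (labels > 0)])
        if hit.size:
            reach = np.isin(labels, hit)
            newly = reach & ~assigned
            out[newly] = v
            assigned |= newly
    return ScalarVolume(out, edt.spacing, edt.origin, role="aedt")
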