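"""Join tree of EDT superlevel sets, with a voxel-to-edge map.

As the probe radius ``r`` decreases, the feasible-center sets ``Void(r)``
grow and merge.  The join tree records this hierarchy: leaves are
(plateau-merged) local maxima of the EDT — pore and cavity centers, or
open boundary regions; branch (saddle) nodes are bottlenecks where two
superlevel components merge, carrying the bottleneck radius as their EDT
value; roots sit at level 0, one per connected component of the void
space.  Every void voxel is mapped to the tree edge whose contour class
contains it, which turns the tree into a lookup index from tree tags back
to the image volume.

Construction sweeps the distinct EDT values in descending order with
union-find.  All voxels of one value are inserted as a batch and merged
among themselves before components are classified, so a flat plateau
containing several would-be maxima produces exactly one leaf and node
values strictly decrease along every leaf-to-root path, which a per-voxel
sweep over tied discrete EDT values would not guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import connectivity_structure
from .volume_io import ScalarVolume

__all__ = ["ContourTree", "TreeNode", "TreeEdge", "build_contour_tree",
           "tree_components_at", "partitions_agree"]


@dataclass
class TreeNode:
    index: int
    voxel: tuple[int, int, int]
    value: float          # EDT value at the critical point, nm
    kind: str             # 'leaf' | 'saddle' | 'root'


@dataclass
class TreeEdge:
    index: int
    upper: int            # node index where the edge opens (higher EDT)
    lower: int = -1       # node index where it closes (filled on close)


@dataclass
class ContourTree:
    nodes: list[TreeNode]
    edges: list[TreeEdge]
    voxel_map: np.ndarray         # per-voxel edge index, -1 on biomass
    spacing: float
    connectivity: int
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    edt: ScalarVolume | None = None   # source field, kept for tagging lookups

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.kind == "leaf"]

    @property
    def saddles(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.kind == "saddle"]

    @property
    def roots(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.kind == "root"]

    def node_edges(self) -> list[list[int]]:
        """Incident edge indices per node."""
        inc: list[list[int]] = [[] for _ in self.nodes]
        for e in self.edges:
            inc[e.upper].append(e.index)
            inc[e.lower].append(e.index)
        return inc

    def to_text(self) -> str:
        """Plain-text dump: one node line and one edge line per element."""
        out = ["# node index kind i j k value_nm"]
        for n in self.nodes:
            out.append(f"node {n.index} {n.kind} {n.voxel[0]} {n.voxel[1]} "
                       f"{n.voxel[2]} {n.value:.9g}")
        out.append("# edge index upper_node lower_node")
        for e in self.edges:
            out.append(f"edge {e.index} {e.upper} {e.lower}")
        return "\n".join(out) + "\n"


def _neighbor_offsets(shape, connectivity):
    struct = connectivity_structure(connectivity)
    offs = np.argwhere(struct) - 1
    offs = offs[np.any(offs != 0, axis=1)]
    flat = offs @ np.array([shape[1] * shape[2], shape[2], 1])
    return offs, flat


def build_contour_tree(edt: ScalarVolume, connectivity: int = 6) -> ContourTree:
    """Build the join tree of the EDT's superlevel sets.

    Ties are resolved by batch insertion per distinct value with
    lexicographic (i, j, k) ordering inside a batch, so the tree is
    deterministic.  Boundary maxima are ordinary leaves (they model probe
    sources outside the field of view).
    """
    if edt.role != "edt":
        raise ValueError(f"expected an EDT volume, got role={edt.role!r}")
    vals = np.asarray(edt.values, dtype=float)
    shape = vals.shape
    flat_vals = vals.ravel()
    void_idx = np.flatnonzero(flat_vals > 0)
    if void_idx.size == 0:
        raise ValueError("empty void space: contour tree undefined")

    _, flat_offs = _neighbor_offsets(shape, connectivity)
    coords_of = lambda fi: tuple(int(c) for c in np.unravel_index(fi, shape))

    # union-find over flat voxel indices
    parent: dict[int, int] = {}
    size: dict[int, int] = {}
    comp_edges: dict[int, set[int]] = {}   # root -> edge ids merged this batch
    min_voxel: dict[int, int] = {}         # root -> lex-smallest member

    def find(i: int) -> int:
        r = i
        while parent[r] != r:
            r = parent[r]
        while parent[i] != r:
            parent[i], i = r, parent[i]
        return r

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        if size[ra] < size[rb]:
            ra, rb = rb, ra
        parent[rb] = ra
        size[ra] += size.pop(rb)
        comp_edges[ra] |= comp_edges.pop(rb)
        min_voxel[ra] = min(min_voxel[ra], min_voxel.pop(rb))

    nodes: list[TreeNode] = []
    edges: list[TreeEdge] = []
    voxel_map = np.full(vals.size, -1, dtype=np.int64)

    def new_node(voxel_flat: int, value: float, kind: str) -> int:
        nodes.append(TreeNode(len(nodes), coords_of(voxel_flat), value, kind))
        return len(nodes) - 1

    def open_edge(upper_node: int) -> int:
        edges.append(TreeEdge(len(edges), upper_node))
        return len(edges) - 1

    # neighbor coordinate-validity: precompute coordinates for bound checks
    zz, yy, xx = np.unravel_index(void_idx, shape)
    order = np.lexsort((xx, yy, zz, -flat_vals[void_idx]))
    sorted_idx = void_idx[order]
    sorted_vals = flat_vals[sorted_idx]
    offs_coords, _ = _neighbor_offsets(shape, connectivity)

    pos = 0
    n = len(sorted_idx)
    while pos < n:
        v = sorted_vals[pos]
        end = pos
        while end < n and sorted_vals[end] == v:
            end += 1
        batch = sorted_idx[pos:end]

        # activate batch voxels, then union with active neighbors
        for fi in batch:
            parent[int(fi)] = int(fi)
            size[int(fi)] = 1
            comp_edges[int(fi)] = set()
            min_voxel[int(fi)] = int(fi)
        bcoords = np.array(np.unravel_index(batch, shape)).T
        for fi, c in zip(batch, bcoords):
            fi = int(fi)
            for off in offs_coords:
                nc = c + off
                if np.any(nc < 0) or np.any(nc >= shape):
                    continue
                nfi = int(nc[0] * shape[1] * shape[2] + nc[1] * shape[2] + nc[2])
                if nfi in parent:
                    union(fi, nfi)

        # classify each component the batch touches
        batch_roots: dict[int, int] = {}   # root -> lex-smallest batch voxel
        for fi in batch:                   # batch is in lex order within value
            r = find(int(fi))
            batch_roots.setdefault(r, int(fi))
        for r, first_voxel in batch_roots.items():
            merged = comp_edges[r]
            if len(merged) == 0:           # born here: plateau-merged maximum
                leaf = new_node(first_voxel, float(v), "leaf")
                comp_edges[r] = {open_edge(leaf)}
            elif len(merged) >= 2:         # bottleneck: components join
                saddle = new_node(first_voxel, float(v), "saddle")
                for eid in sorted(merged):
                    edges[eid].lower = saddle
                comp_edges[r] = {open_edge(saddle)}
            # len == 1: plain growth, keep the edge

        # map batch voxels to their component's current edge
        for fi in batch:
            (eid,) = comp_edges[find(int(fi))]
            voxel_map[int(fi)] = eid
        pos = end

    # close remaining edges at roots (level 0, biomass-adjacent components)
    for r in sorted({find(int(fi)) for fi in sorted_idx}):
        root = new_node(min_voxel[find(r)], 0.0, "root")
        (eid,) = comp_edges[find(r)]
        edges[eid].lower = root

    return ContourTree(nodes, edges, voxel_map.reshape(shape), edt.spacing,
                       connectivity, np.asarray(edt.origin, dtype=float), edt)


def tree_components_at(tree: ContourTree, edt: ScalarVolume,
                       r: float) -> tuple[np.ndarray, int]:
    """Partition ``Void(r)`` into components using only the tree index.

    Returns a label volume (0 background, 1..K components) equal, up to
    label renumbering, to ``connected_components(threshold_void(edt, r))``
    — the tree is a lossless index of superlevel connectivity.
    """
    if r < 0:
        raise ValueError(f"radius must be nonnegative, got {r}")
    nodes, edges = tree.nodes, tree.edges
    # union-find over tree nodes above level r
    parent = {n.index: n.index for n in nodes if n.value > r}

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for e in edges:
        if nodes[e.upper].value > r and nodes[e.lower].value > r:
            parent[find(e.upper)] = find(e.lower)

    comp_of_node = {i: find(i) for i in parent}
    labels_of_root: dict[int, int] = {}
    edge_label = np.zeros(len(edges), dtype=np.int64)
    for e in edges:
        if nodes[e.upper].value > r:
            root = comp_of_node[e.upper]
            lbl = labels_of_root.setdefault(root, len(labels_of_root) + 1)
            edge_label[e.index] = lbl

    vals = np.asarray(edt.values, dtype=float)
    out = np.zeros(vals.shape, dtype=np.int64)
    sel = vals > r
    out[sel] = edge_label[tree.voxel_map[sel]]
    return out, len(labels_of_root)


def partitions_agree(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label volumes define the same partition of their support."""
    if (a > 0).sum() != (b > 0).sum() or not np.array_equal(a > 0, b > 0):
        return False
    sel = a > 0
    pairs = np.unique(np.stack([a[sel], b[sel]]), axis=1)
    return (len(np.unique(pairs[0])) == pairs.shape[1]
            and len(np.unique(pairs[1])) == pairs.shape[1])
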