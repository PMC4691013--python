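# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic tests demonstrate.

## Model and assumptions

The catalyst is modeled as a rigid sphere of radius r diffusing through
void space from a seed region Σ. Accessibility is purely geometric: no
chemistry, no deformation of probe or wall, no time resolution. The
segmentation is taken as ground truth — biomass vs void (lumen counts as
void), on an isotropic voxel grid with spacing in nm. Arrays are stored
`(z, y, x)` with z the axial/section axis; voxel centers sit at
`origin + spacing · (i, j, k)`. Anisotropic grids are rejected (relative
tolerance 1e-3) rather than resampled.

The chain of quantities:

1. `EDT(x) = min{|x − y| : y ∈ Biomass}` — exact Euclidean distances
   between voxel centers (scipy's exact EDT). The grid boundary is open
   void: edge voxels measure distance only to in-grid biomass, which is
   what lets the boundary act as a probe source. Exactness matters because
   EDT values become bottleneck radii downstream; a chamfer approximation
   would bias them.
2. `Void(r) = {EDT > r}` (strict), so `Void(0)` is exactly the void space.
3. The join tree of EDT superlevel sets. Only the join structure is built
   (not the full contour tree with splits): accessibility needs the merging
   of superlevel components as r decreases; EDT minima over void play no
   role in the tagging.
4. Accessibility tagging from Σ, then `aEDT = min(EDT, tag)` per voxel.
5. `aCRT = ` maximal-sphere painting of the aEDT.
6. Marching-cubes surface, ε-ball vertex sampling of the aCRT, and the
   accessible-area curve.

## Discrete path semantics

A probe path is a chain of face-adjacent (6-connected) void voxels by
default. 6-connectivity is the physically conservative choice — a sphere
of positive radius cannot pass through an edge- or corner-only contact —
but every stage (components, tree, tagging, oracles) accepts 26 for
sensitivity analysis; the choice shifts bottleneck radii by up to a voxel
diagonal. The discrete aEDT is the max over such paths of the min EDT
along the path, endpoints included. The contour-tree route reproduces this
exactly (verified voxelwise against two independent oracles on irregular
masks at both connectivities).

## Tagging algorithm

The three-step scheme — pick seed parts of the tree, tag the descent to
the roots with the EDT itself, then give each untagged subtree the value
of the branch node that attaches it — assumes seeds sit at leaves. Real
seeds are arbitrary voxel sets (a thin lumen sliver may lie at low EDT),
so tagging is implemented as max-min propagation over the tree graph:
every edge containing a seed voxel starts with capacity equal to the best
seed EDT on it, and capacities propagate across nodes, each node value
capping what passes (bottleneck Dijkstra; the tree is tiny, so cost is
negligible). With seeds at leaves this reduces literally to the three
steps. The per-voxel lookup is `min(EDT, tag)`, not `max`: a probe must
both pass the guarding bottleneck *and* fit at the voxel, and `min` is the
only reading consistent with the widest-path definition and with uniform
cavity labeling in the aCRT. Void unreachable at any positive radius gets
aEDT = 0, which keeps the area integrand well defined.

Ties in the discrete EDT are ubiquitous (squared distances are integers),
so the tree is built by descending sweep over *batches* of equal value:
all voxels of one value are inserted and merged before components are
classified as new leaf (a plateau-merged maximum), growth, or saddle.
This guarantees one leaf per maximal plateau and strictly decreasing node
values along every leaf-to-root path; within a batch, lexicographic
(i, j, k) order fixes node locations deterministically. Boundary maxima
are ordinary leaves (possible probe sources outside the field of view).
Roots sit at level 0, one per void component.

## Covering transform

Painting follows the maximal-sphere definition: each void voxel x paints
`{y : |y − x| ≤ D(x)}` (physical distance, inclusive, clipped at the
domain boundary) with value `D(x)`, keeping the pointwise max — so the
result is independent of visiting order. Centers are processed in groups
of equal radius, largest first, so each group needs one ball stencil and
no repainting. One deliberate restriction: painting writes only where
`D > 0`. With center-to-center distances, the maximal sphere's boundary
passes exactly through the nearest biomass voxel center, and an
unrestricted inclusive test would smear positive radii onto biomass; a
probe overlaps the void it covers, not the wall it rests against. CRT and
aCRT are therefore 0 exactly on biomass (and on unreachable void, which
no sphere from the reachable region can cover).

Non-redundant centers: x is redundant when some x′ has
`D(x′) ≥ D(x) + |x − x′|` (its sphere lies inside x′'s). Containment is
transitive, so dropping every dominated center is safe; painting from the
surviving ridge centers must equal — and is tested voxelwise equal to —
the full paint. Pruning is optional and off by default.

## Surface extraction and sampling

Marching cubes runs at iso-level 0.5 on the biomass indicator after a
light Gaussian smoothing of sigma = 0.5 voxel. On raw binary data the
staircase triangulation overestimates a voxelized sphere's area by ~8.5%;
sigma 0.5 brings a radius-20-voxel sphere to +3.8% and an axis-aligned box
to −4.0% of their analytic areas while displacing vertices by under half a
voxel. If smoothing removes the iso-crossing entirely (features thinner
than the kernel, e.g. a single-voxel grain), the binary field is used
unsmoothed so no surface is ever lost. Domain-boundary cuts are left open:
they are artifacts of the field of view, not biomass surface.

Vertex accessibility is the max aCRT over voxel centers within ε of the
vertex — deliberately *not* interpolation, which mixes in the zeros just
inside the biomass and is meaningless at a discontinuity. ε defaults to
1.1 voxel widths: large enough that every marching-cubes vertex (which
lies on a grid edge) sees at least two voxel centers and partial-volume
zeros cannot dominate, small enough not to inflate accessibility.
ε ≤ 0 is rejected.

A triangle counts as accessible at radius r when all three vertices have
accessibility ≥ r (conservative, biases the curve low); a mean-vertex rule
is available. The default radius grid is 0 plus every distinct positive
vertex value — the exact step curve; any sorted grid can be supplied for
plotting. Curves are emitted as raw area (nm²), fraction of total surface
area, and area per biomass volume (1/µm) — the literature uses both
normalizations, so both are kept.

## Phantoms: what they emulate, and what they do not

Phantoms are rasterized by voxel-center inclusion, so recovered radii
carry a discretization error up to about one voxel (e.g. a radius-3
channel yields a discrete saddle at √10 ≈ 3.16); tolerances of ±1 voxel
in tests reflect that bound, not algorithmic slack.

- `sphere_pore` — covering-radius semantics (CRT = R throughout a pore).
- `dumbbell` — two cavities, one bottleneck of known radius a; openings to
  the boundary and an optional lumen sliver at the mouth.
- `delaminated_slab` — planar gaps inside a wall that touch the axial
  boundary but not the lumen, the geometry behind the lumen-vs-boundary
  seeding gap; optional necks of known radius reconnect them.
- `rough_wall` — a corrugated height-field wall (cosine along x, constant
  along z, random phase) below an open lumen: surface texture with
  provably no bottlenecks, so all seed strategies must coincide exactly.
- `random_blobs` — thresholded smoothed Gaussian noise at a target
  porosity; the stress geometry for oracle-equivalence tests.

All generators are deterministic given their parameter record and seed. What passing
these tests does *not* show: real tomograms have anisotropic texture,
partial-volume gradations, segmentation errors, and missing-wedge
artifacts; none are modeled. The phantoms validate the geometry engine,
not the segmentation step, which here is only a global-threshold baseline
(dark = biomass, with an invert flag) intended for clean two-phase data.

## Problem sizes

Oracle-equivalence checks run on 16³–24³ grids (the quadratic double-loop
painting oracle and the Python-level Dijkstra oracle make larger grids
pointless for validation), bottleneck-recovery and surface checks on 48³–64³
phantoms. The production path itself is vectorized (grouped painting,
array sweeps) and handles much larger volumes; only the reference oracles
are size-limited.

## Known limitations

- Spherical probes only; no flexible or multi-domain catalyst models.
- Accessibility is binary per (point, radius): no diffusion kinetics,
  concentration, or probability.
- The segmentation is trusted; threshold segmentation is provided only as
  a baseline, and interactive semi-automatic segmentation is out of scope.
- Boundary seeding is an upper bound and lumen seeding a lower bound on
  true accessibility for thin sections; the gap between them is a property
  of the imaging geometry, not of the algorithm.
- MRC/NRRD I/O covers the single-volume isotropic case (MRC modes
  0/1/2/6, NRRD raw encoding), not the formats' full generality.
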