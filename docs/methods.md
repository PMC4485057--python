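# Methods

`neuroprint` converts traced neuronal morphologies (points + diameters, in
microns) into watertight, optionally colored, 3D-printable triangle meshes.
This note records the models, conventions, and numerical choices behind each
stage, and what the synthetic fixtures do and do not establish.

## Morphology model and file handling

A morphology is a tree of **sections**: unbranched polylines of 3D points
with per-point diameters. SWC type codes map 1→soma, 2→axon, 3→basal
dendrite, 4→apical dendrite; codes ≥ 5 are preserved as `custom` and treated
like dendrites downstream. One section is created per unbranched run of
same-type SWC nodes. A single-node soma is modeled as a sphere; multi-node
somata as frustum chains (the familiar "cylinder soma" of many repository
files). The restricted Neurolucida ASC dialect supports a `CellBody` contour
block plus `Axon`/`Dendrite`/`Apical` trees with `|`-separated daughters;
a contour soma is summarized as an area-equivalent sphere at the contour
centroid for meshing and SWC export.

Sections store only their own tracing nodes; the attachment to the parent is
the pair `(parent_id, parent_point_index)`. The surface generator emits an
explicit *bridge frustum* across any gap between a section's first point and
its attachment point, so the meshed union stays connected without moving any
measured coordinate. Bridges from a soma run at the child's radius (a
dendrite should not flare to soma size); bridges between neurites taper from
the parent point's radius to the child's.

**Repair.** Tracings whose neurite roots have parent −1 (or a dangling
parent id) are flagged at load. Repair prepends a single point at the soma's
volume-weighted center of mass, at the root's first-point diameter —
measured coordinates are canonical and are never moved. Other tracing
defects (zero diameters, slice amputation) are surfaced by the fixtures and
validators but deliberately not auto-fixed; deciding whether an amputated
arbor is acceptable is a judgment call, not an algorithm.

**Morphometrics convention.** All counts exclude the soma. Stems are neurite
sections attached directly to the soma (or parentless roots). A branch point
is a neurite node with ≥ 2 outgoing edges in the tree rooted at the soma; a
branch is a maximal unbranched path between soma, branch points, and
terminations, so on a tree whose branch points are all bifurcations

    n_branches = 2 · n_branch_points + n_stems.

This is the identity a motoneuron-scale tree satisfies with 181 branch
points, 8 stems → 370 branches. Total length sums 3D point-to-point
distances over neurite points, including attachment edges between neurite
sections; soma-to-neurite gaps are excluded. With the soma excluded
throughout, SWC (node soma) and ASC (contour soma) encodings of one cell
yield identical statistics.

## Diameter policies and scaling

Printers bound the minimum thickness of wirey structures, so neurite
diameters are edited before meshing — never the coordinates, so lengths are
exactly preserved. Policies: `fixed` (set), `scale` (multiply), `floor`
(raise to a minimum), and `per_kind` maps (e.g. axon fixed 6 µm, dendrites
fixed 9 µm — a configuration that makes axon and dendrites distinguishable
in the print). The soma is never touched by diameter policies; instead
`scale_soma` multiplies soma positions *and* diameters by one factor and
repositions the result so its volume-weighted center of mass is unchanged.
The center of mass is computed from analytic primitive volumes and
centroids (sphere; frustum centroid at height h(r₀²+2r₀r₁+3r₁²)/(4(r₀²+r₀r₁+r₁²))
from the r₀ end), volume-weighted over the chain. Dendrite attachment points
are not re-anchored to the scaled soma surface; the watertight union absorbs
any overlap or gap.

`scale_model` multiplies all coordinates (and diameters) by a coordinate
scale s. For µm input read by printer software as mm, the magnification is
s × 1000 (s = 0.2 → 200×) and a feature d µm across prints d·s mm.

## Watertight tessellation

Each consecutive point pair is a frustum; single-point sections are spheres.
The surface is the zero level set of the **exact signed distance field of
the primitive union**, sampled on a uniform grid and polygonized by marching
cubes. The SDF per capped cone is the standard exact closed form (lateral
surface and flat caps); the union is the pointwise minimum, evaluated only
inside each primitive's padded bounding box for speed (exact wherever it
matters). Because the construction is local, interpenetrating neurites —
within one cell or across a merged multi-cell cluster — produce a single
unified watertight surface, and disjoint cells remain separate bodies.

Numerical choices:

* **Grid pitch** defaults to half the smallest neurite radius; a pitch
  larger than that radius raises an error naming the offending radius.
  Grid bounds are padded by twice the largest radius.
* **Refinement.** Marching cubes inscribes the surface, so enclosed volume
  is biased low by the chordal deficit (≈ 7% for a cylinder sampled at half
  its radius). After extraction, vertices are Newton-projected onto the
  exact union SDF (gradient of the nearest primitive, steps clamped to 0.4
  pitch to avoid folding at creases), then midpoint-subdivided and
  re-projected. Two refinement levels (the default) bring cylinder, sphere
  and frustum volumes within ~1% of the analytic values at the default
  pitch, and the error decreases monotonically as the pitch is halved.
* **Degenerate shells.** Where two surfaces pass tangentially the grid can
  emit single-voxel shells that projection flattens to zero volume; shells
  with |volume| far below one voxel are dropped. Genuine interior voids
  (pockets enclosed between near-touching dendrites) are kept: they carry
  inward-oriented shells whose signed volume correctly subtracts from the
  printed volume, and body counting treats them as part of the enclosing
  solid rather than as separate components.
* Orientation is normalized so the divergence-theorem volume is positive;
  sphere-like joins at branch points are implicit in the SDF minimum, with
  no explicit fillets.

Grid sampling limits orientation independence: rotating the input rotates
the mesh, with enclosed volume reproducible to roughly 10⁻³ relative at the
default pitch (tighter at finer pitch), not to machine precision.

## Triangle-to-segment mapping and color

The tessellation does not remember which frustum generated which triangle,
so structure-based coloring maps each face centroid back: among frusta that
*contain* the centroid, pick the one containing it by the least amount —
formalized as the smallest Euclidean distance from the centroid to that
frustum's boundary (lateral surface or caps, whichever is nearer); if no
frustum contains it, pick the frustum with the closest surface. Exact ties
break by lowest section id, then lowest point index, making the assignment
total and deterministic. Whether "inside by the least amount" should instead
be read radially is an open reading; the nearest-boundary choice is
documented here as this package's definition. Colors are then assigned per
face: by section kind, by section name, or by a scalar field
(section/point → value) rendered by piecewise-linear interpolation between
colormap stops over the observed range.

## Serialization and metadata

Binary STL is the default (80-byte header, little-endian uint32 count,
50 bytes/triangle — a 12-triangle cube is exactly 684 bytes); ASCII STL
is behind a flag; normals are recomputed from winding. STL cannot carry
color: writing a colored mesh logs a warning and emits geometry only.
VRML97 (`.wrl`) carries per-face color (`colorPerVertex FALSE`), matching
the per-face segment mapping. Both formats are unitless; the output unit
(mm after scaling), magnification, printed volume (divergence-theorem sum
of signed tetrahedra), axis-aligned bounding box, algorithm name, creator,
date and a unique id travel in a JSON sidecar — the cost-relevant metadata
a printing catalogue records.

## Printability validation

Thickness is validated on the **logical skeleton**, not the mesh: the
tessellated surface can run slightly thinner than the skeleton radii, so a
skeleton check is conservative and resolution-independent. Printed diameter
of a point = diameter (µm) × coordinate scale, read in mm. Defaults follow
commercial SLS practice: hard minimum 1.0 mm for wirey structures,
recommended 1.2 mm (submitting at the recommendation avoids borderline
rejections); `suggest_diameter` inverts the formula
(recommended / scale, e.g. 6 µm at 200×, 1.5 µm at 800×). The soma is
exempt from wirey rules but counts toward the bounding box. Structural
risks — long unbranched printed runs (default threshold 100 mm), a heavy
soma on thin stems — are advisories only: printers reject such models at
their own discretion and no quantitative pass/fail criterion is claimed.
Comparisons carry a 10⁻⁹ relative slack so a diameter solved exactly for a
threshold passes it.

## Synthetic fixtures

The generators provide ground truth without downloads, all drawn from one
seeded NumPy `default_rng` so outputs are byte-identical across platforms:

* `gen_tree` grows exactly the requested number of stems and bifurcations
  (every branch point is a bifurcation), with segment lengths uniform in
  8–15 µm, child diameters tapering by 0.9 per branch, 2 µm stems and a
  12 µm soma — values in the range of repository tracings at dendrite
  scale. It records total drawn length and summed analytic frustum volume
  (including soma bridges) for exact cross-checks.
* `gen_defective` injects one named defect — a detached root (shifted off
  the soma, parent −1), a zero diameter, or slab amputation with z-extent
  truncation — changing only the targeted property.
* `gen_cluster` builds n distinct cells on a soma ring whose apical
  dendrites all end 1 µm *past* a shared convergence point along their own
  approach directions, so every apical frustum strictly contains that point
  and the merged mesh is one connected component by construction — a
  miniature analogue of mitral cells converging on a glomerulus, with
  interleaved lateral dendrites.

These fixtures guarantee topological and geometric ground truth, not
biological realism: no realistic branch-angle or caliber statistics, no
spines, no cell-type-specific arbor shapes. Tests passing on them establish
the correctness of parsing, repair, counting, tessellation, mapping and
export — not that any particular real cell prints well.

## Problem sizes

The default verification workloads are desk-scale: primitives of radius
1–5 µm meshed at 0.25–0.5 µm pitch (thousands to tens of thousands of
faces), a five-cell cluster of ~90 k faces meshed without subdivision
refinement, Monte-Carlo union volumes with 10⁶ samples, and a
motoneuron-scale counting tree of 181 bifurcations. Full-size cells mesh
with the same code; pitch and refinement are the knobs that trade accuracy
for time and memory.

## Known limitations

* The ASC reader covers the restricted dialect only (no markers, spines,
  or the full Neurolucida grammar); unknown top-level blocks are skipped
  with a warning.
* Multi-cell coloring uses the first cell's section table; per-cell color
  schemes for clusters require mapping cells separately.
* No mesh decimation: triangle counts grow with refinement level; export
  size is the trade-off.
* Anisotropic scaling, printer-material shrink compensation, support
  structures, and cost estimation are out of scope.
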