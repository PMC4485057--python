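# neuroprint

Turn traced neuronal morphologies into watertight, colorable, 3D-printable
surface meshes.

Tens of thousands of neuron tracings are freely available (NeuroMorpho.Org,
ModelDB, Neurolucida exports), each a skeleton of 3D points with diameters.
`neuroprint` converts such a skeleton into a physical object: it repairs
common tracing defects (dendrites detached from the soma), thickens
neurites to printable diameters while preserving their lengths, rescales
the soma about its center of mass, tessellates a single watertight surface
of the frustum union — robust to interpenetrating dendrites within one cell
or across a merged microcircuit — maps surface triangles back to the
skeleton for region- or property-based coloring, validates the model
against printer thickness rules, and exports STL / VRML97 plus a metadata
record (magnification, printed volume, bounding box).

It is aimed at researchers and educators who want to hold, compare, and
teach with physical neurons, and at anyone curating a catalogue of
printable reconstructions.

## The model in brief

A morphology is a tree of sections — unbranched polylines of points
`(x, y, z, d)` in µm. Every consecutive point pair defines a frustum
(truncated cone) with end radii `d/2`; a single-point soma is a sphere. The
printable surface is the boundary of the union of all frusta and spheres,
extracted as the zero level set of the exact signed distance field

    f(p) = min over primitives of sdf_primitive(p)

sampled on a uniform grid, polygonized by marching cubes, and polished by
projecting vertices back onto `f = 0` with one–two midpoint subdivisions.
Because the union is computed locally, dendrites that pass through each
other simply merge into one surface — the property that makes multi-cell
clusters printable in one piece.

Scaling is linear: for morphologies in µm and printer software expecting
mm, multiplying coordinates by `s` gives a magnification of `1000·s`
(`s = 0.2` → 200×), and a neurite of `d` µm prints `d·s` mm thick. Printers
typically require ≥ 1 mm for wire-like structures; submitting at 1.2 mm is
safer, which at 200× means 6 µm dendrites (`suggest_diameter` computes
this for any spec).

Branch counting excludes the soma: a branch point is a neurite node with
two or more daughters, a stem is a neurite attached directly to the soma,
and on trees whose branch points are all bifurcations
`branches = 2·branch_points + stems` (181 branch points on 8 stems ↔ 370
branches, the arithmetic of a cat spinal motoneuron reconstruction).

## Worked example

```sh
# generate a reproducible synthetic cell (7 bifurcations on 2 stems)
neuroprint fixtures --seed 5 --bifurcations 7 --stems 2 -o cell.swc
# -> cell.swc: 7 branch points, 16 branches, 2 stems

# raw tracing diameters are far too thin to print at 200x
neuroprint check cell.swc --scale 0.2
# -> FAIL: 48 violation(s), 0 advisory point(s)
#    section 2: min printed diameter 0.400 mm ...   (exit code 2)

# fix the dendrites at 6 um (prints 1.2 mm at 200x) and mesh
neuroprint mesh cell.swc -o cell.stl --fixed-diameter 6 --scale 0.2
# -> cell.stl: 207200 faces, volume 121.734 mm^3, magnification 200x

neuroprint stats cell.stl
# -> volume: 121.734
#    surface area: 398.15
#    bbox min: (-5.858612, -9.217735, -8.298014)
#    bbox max: (32.102764, 6.512812, 9.424968)
#    components: 1
```

The printed volume and bounding box are the quantities commercial services
price on; `components: 1` confirms the cell meshed as a single watertight
body. The same library calls are available in Python
(`read_swc`, `repair_detached`, `apply_diameter_policy`, `tessellate`,
`map_triangles_to_segments`, `write_wrl`, …), and `neuroprint run
--config run.yaml` executes the whole pipeline reproducibly from one
config file, writing a manifest alongside the outputs.

To color by structure, map triangles back to the skeleton and export WRL
(STL cannot carry color and will say so):

```python
import neuroprint as npr

cell = npr.repair_detached(npr.read_swc("cell.swc"))
mesh = npr.tessellate(cell)
assign = npr.map_triangles_to_segments(mesh, npr.skeleton_to_frusta(cell))
scheme = npr.ColorScheme(mode="by_kind",
                         kind_map={"axon": (1, 0, 0), "dendrite": (1, 1, 1)})
npr.write_wrl(npr.assign_colors(mesh, assign, scheme, cell), "cell.wrl")
```

### Checking a repository tracing

`branch_stats` reproduces catalogue morphometrics on real accessions. For
example, after downloading the SWC for NeuroMorpho.Org accession NMO_00607
(a cat spinal motoneuron):

```python
stats = npr.branch_stats(npr.repair_detached(npr.read_swc("NMO_00607.swc")))
# expected: 181 branch points, 370 branches, 8 stems
```

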