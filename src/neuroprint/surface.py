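"""Watertight surface tessellation of point-and-diameter skeletons.

Each pair of consecutive tracing points becomes a frustum (truncated cone);
single-point sections (e.g. a spherical soma) become spheres.  The surface of
the *union* of all primitives — across one or many cells — is extracted by
sampling the exact signed distance field of the union on a uniform grid and
running marching cubes at the zero level set.

This construction is local and therefore robust to interpenetrating neurites:
dendrites passing close to each other, from the same cell or different cells,
merge into a single unified watertight surface, and the mesh converges to the
true union as the grid pitch shrinks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from skimage.measure import marching_cubes

from .errors import MeshingError
from .mesh import TriangleMesh
from .morphology import SOMA, Morphology

logger = logging.getLogger(__name__)


@dataclass
class Frustum:
    """Truncated cone between two consecutive tracing points.

    ``p0 == p1`` encodes a sphere of radius ``r0`` (degenerate axis).
    ``section_id``/``point_index`` record provenance: the frustum ends at
    ``points[point_index]`` of its section (index 0 for the bridge frustum
    that connects a section's first point to its parent).
    """

    p0: np.ndarray
    p1: np.ndarray
    r0: float
    r1: float
    section_id: int
    point_index: int
    kind: str = "basal_dendrite"

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.r0 <= 0 or self.r1 <= 0:
            raise MeshingError(
                f"non-positive radius on section {self.section_id} "
                f"point {self.point_index}"
            )

    @property
    def is_sphere(self) -> bool:
        return bool(np.all(self.p0 == self.p1))

    @property
    def max_radius(self) -> float:
        return max(self.r0, self.r1)

    def aabb(self):
        lo = np.minimum(self.p0 - self.r0, self.p1 - self.r1)
        hi = np.maximum(self.p0 + self.r0, self.p1 + self.r1)
        return lo, hi

    def volume(self) -> float:
        """Analytic volume of the isolated primitive."""
        if self.is_sphere:
            return (4.0 / 3.0) * math.pi * self.r0**3
        h = float(np.linalg.norm(self.p1 - self.p0))
        return math.pi * h * (self.r0**2 + self.r0 * self.r1 + self.r1**2) / 3.0

    def sdf(self, points: np.ndarray) -> np.ndarray:
        """Exact signed distance from ``points`` (N, 3) to this primitive.

        Negative inside; flat caps count as boundary.
        """
        points = np.asarray(points, dtype=float)
        if self.is_sphere:
            return np.linalg.norm(points - self.p0, axis=-1) - self.r0
        ba = self.p1 - self.p0
        baba = float(ba @ ba)
        pa = points - self.p0
        paba = (pa @ ba) / baba  # normalized axial coordinate
        rad2 = np.maximum(np.einsum("...i,...i->...", pa, pa) - paba**2 * baba, 0.0)
        x = np.sqrt(rad2)  # radial distance from the axis
        rba = self.r1 - self.r0
        cax = np.maximum(x - np.where(paba < 0.5, self.r0, self.r1), 0.0)
        cay = np.abs(paba - 0.5) - 0.5
        k = rba * rba + baba
        f = np.clip((rba * (x - self.r0) + paba * baba) / k, 0.0, 1.0)
        cbx = x - self.r0 - f * rba
        cby = paba - f
        s = np.where((cbx < 0.0) & (cay < 0.0), -1.0, 1.0)
        return s * np.sqrt(
            np.minimum(cax**2 + cay**2 * baba, cbx**2 + cby**2 * baba)
        )


@dataclass
class MeshResolution:
    """Sampling resolution for tessellation.

    ``spatial_step`` is the grid pitch in the morphology's units; ``None``
    selects half the smallest neurite radius.  ``refine_levels`` midpoint
    subdivisions (each followed by Newton projection of the vertices onto the
    exact union distance field) polish away the chordal volume deficit of
    marching cubes; two levels bring primitive volumes within ~1% of the
    analytic values at the default pitch.  ``angular_step`` is kept for
    alternative tessellation backends and is unused by the grid backend.
    """

    spatial_step: Optional[float] = None
    refine_levels: int = 2
    angular_step: float = math.pi / 8


_EPS_LEN = 1e-12


def skeleton_to_frusta(m: Morphology) -> List[Frustum]:
    """Decompose a morphology into sphere/frustum primitives.

    One frustum per consecutive point pair per section; single-point sections
    become spheres.  When a section's first point does not coincide with its
    attachment point on the parent, an explicit bridge frustum is added so the
    union stays connected (soma parents bridge at the child's radius so the
    neurite does not flare to soma size).
    """
    out: List[Frustum] = []
    by_id = {s.id: s for s in m.sections}
    for sec in m.sections:
        if len(sec.points) == 0:
            raise MeshingError(f"section {sec.id} has no points")
        pts = sec.xyz()
        radii = 0.5 * sec.diameters()
        # bridge to the parent attachment point
        if sec.parent_id is not None and sec.parent_id in by_id:
            parent = by_id[sec.parent_id]
            attach = parent.points[sec.parent_point_index]
            gap = np.linalg.norm(sec.points[0].xyz - attach.xyz)
            if gap > _EPS_LEN:
                r_near = radii[0] if parent.is_soma else 0.5 * attach.diameter
                out.append(
                    Frustum(
                        attach.xyz,
                        pts[0],
                        r_near,
                        radii[0],
                        section_id=sec.id,
                        point_index=0,
                        kind=sec.kind,
                    )
                )
        if len(sec.points) == 1:
            out.append(
                Frustum(
                    pts[0], pts[0], radii[0], radii[0],
                    section_id=sec.id, point_index=0, kind=sec.kind,
                )
            )
            continue
        for i in range(len(pts) - 1):
            if np.linalg.norm(pts[i + 1] - pts[i]) <= _EPS_LEN:
                continue  # zero-length segment carries no volume of its own
            out.append(
                Frustum(
                    pts[i], pts[i + 1], radii[i], radii[i + 1],
                    section_id=sec.id, point_index=i + 1, kind=sec.kind,
                )
            )
    return out


def _grid_axes(lo, hi, step):
    axes = []
    for d in range(3):
        n = max(int(math.ceil((hi[d] - lo[d]) / step)) + 1, 2)
        axes.append(lo[d] + step * np.arange(n))
    return axes


def sample_sdf(frusta: Sequence[Frustum], step: float, pad: float):
    """Sample the union SDF on a uniform grid covering all primitives.

    Returns ``(field, origin)``.  The field is exact within each primitive's
    padded bounding box and a large positive constant elsewhere, which is
    sufficient for extracting the zero level set of the union.
    """
    los, his = zip(*(f.aabb() for f in frusta))
    lo = np.min(los, axis=0) - pad
    hi = np.max(his, axis=0) + pad
    ax = _grid_axes(lo, hi, step)
    shape = tuple(len(a) for a in ax)
    n_voxels = int(np.prod(shape))
    if n_voxels > 2.5e8:
        raise MeshingError(
            f"tessellation grid of {n_voxels} voxels exceeds the supported "
            f"size; increase spatial_step"
        )
    field = np.full(shape, 8.0 * step)
    for f in frusta:
        flo, fhi = f.aabb()
        idx = []
        for d in range(3):
            i0 = max(int(np.searchsorted(ax[d], flo[d] - 3 * step)) - 1, 0)
            i1 = min(int(np.searchsorted(ax[d], fhi[d] + 3 * step)) + 1, shape[d])
            idx.append((i0, i1))
        sub = np.meshgrid(
            ax[0][idx[0][0]:idx[0][1]],
            ax[1][idx[1][0]:idx[1][1]],
            ax[2][idx[2][0]:idx[2][1]],
            indexing="ij",
        )
        pts = np.stack(sub, axis=-1)
        d = f.sdf(pts.reshape(-1, 3)).reshape(pts.shape[:-1])
        region = field[idx[0][0]:idx[0][1], idx[1][0]:idx[1][1], idx[2][0]:idx[2][1]]
        np.minimum(region, d, out=region)
    return field, lo


def tessellate(
    cells, res: Optional[MeshResolution] = None
) -> TriangleMesh:
    """Build one watertight triangle mesh of the union of all cells' frusta.

    ``cells`` is a morphology or a list of morphologies.  Raises
    :class:`MeshingError` when the grid pitch is too coarse to resolve the
    thinnest neurite.
    """
    if isinstance(cells, Morphology):
        cells = [cells]
    if not cells:
        raise MeshingError("no cells to tessellate")
    res = res or MeshResolution()

    frusta: List[Frustum] = []
    for cell in cells:
        frusta.extend(skeleton_to_frusta(cell))
    if not frusta:
        raise MeshingError("no geometric primitives to tessellate")

    neurite_radii = [
        r for f in frusta if f.kind != SOMA for r in (f.r0, f.r1)
    ]
    min_r = min(neurite_radii) if neurite_radii else min(
        min(f.r0, f.r1) for f in frusta
    )
    step = res.spatial_step if res.spatial_step is not None else 0.5 * min_r
    if step > min_r:
        raise MeshingError(
            f"spatial_step {step} is too coarse to resolve the thinnest "
            f"neurite (radius {min_r}); use a step <= {min_r}"
        )
    max_r = max(f.max_radius for f in frusta)
    pad = 2.0 * max_r + 2.0 * step

    field, origin = sample_sdf(frusta, step, pad)
    try:
        verts, faces, _, _ = marching_cubes(field, level=0.0, spacing=(step,) * 3)
    except ValueError as exc:
        raise MeshingError(f"no surface found at this resolution: {exc}") from None
    mesh = TriangleMesh(vertices=verts + origin, faces=faces)
    mesh = _refine(mesh, frusta, step, res.refine_levels)
    mesh = _drop_degenerate_shells(mesh, step)
    _orient_outward(mesh)
    logger.info(
        "tessellated %d primitives at step %.4g into %d faces",
        len(frusta), step, mesh.n_faces,
    )
    return mesh


def _union_sdf(frusta: Sequence[Frustum], pts: np.ndarray, pad: float):
    """Union SDF (and nearest-primitive index) at ``pts``.

    Exact wherever the true distance is below ``pad``: frusta are culled by
    padded bounding box, which cannot change the minimum for points within
    ``pad`` of the union surface — the only points the refinement evaluates.
    """
    d = np.full(len(pts), pad)
    winner = np.full(len(pts), -1, dtype=np.int64)
    for j, f in enumerate(frusta):
        lo, hi = f.aabb()
        mask = np.all((pts >= lo - pad) & (pts <= hi + pad), axis=1)
        if not mask.any():
            continue
        dj = f.sdf(pts[mask])
        sub = d[mask]
        better = dj < sub
        sub[better] = dj[better]
        d[mask] = sub
        w = winner[mask]
        w[better] = j
        winner[mask] = w
    return d, winner


def _project_vertices(
    verts: np.ndarray, frusta: Sequence[Frustum], step: float, iters: int = 4
) -> np.ndarray:
    """Newton-project vertices onto the zero level set of the union SDF.

    The gradient of a min-union equals the gradient of the nearest primitive
    almost everywhere, so each vertex only differentiates its winner.
    """
    eps = 1e-3 * step
    v = verts
    for _ in range(iters):
        d, winner = _union_sdf(frusta, v, pad=4.0 * step)
        g = np.zeros_like(v)
        for j in np.unique(winner):
            if j < 0:
                continue
            sel = winner == j
            f = frusta[j]
            pts = v[sel]
            for ax in range(3):
                e = np.zeros(3)
                e[ax] = eps
                g[sel, ax] = (f.sdf(pts + e) - f.sdf(pts - e)) / (2 * eps)
        n2 = np.einsum("ij,ij->i", g, g)
        n2[n2 == 0] = 1.0
        # clamped steps keep the projection from folding faces at creases
        move = np.clip(d / n2, -0.4 * step, 0.4 * step)
        v = v - move[:, None] * g
    return v


def _refine(
    mesh: TriangleMesh, frusta: Sequence[Frustum], step: float, levels: int
) -> TriangleMesh:
    """Subdivide and project the marching-cubes mesh onto the exact union.

    Marching cubes inscribes the surface, so enclosed volume is biased low by
    the chordal deficit; midpoint subdivision plus projection converges the
    mesh to the true union surface without changing its topology.
    """
    import trimesh.remesh

    v = _project_vertices(mesh.vertices, frusta, step)
    f = mesh.faces
    for _ in range(levels):
        v, f = trimesh.remesh.subdivide(v, f)
        v = _project_vertices(v, frusta, step)
    return TriangleMesh(vertices=v, faces=f)


def _orient_outward(mesh: TriangleMesh) -> None:
    """Flip face winding if the divergence-theorem volume comes out negative."""
    tri = mesh.triangles()
    vol6 = np.einsum(
        "ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
    ).sum()
    if vol6 < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()


def _drop_degenerate_shells(mesh: TriangleMesh, step: float) -> TriangleMesh:
    """Remove face components with essentially zero enclosed volume.

    Grid sampling can emit single-voxel shells where two surfaces pass
    tangentially; projection flattens them to zero thickness.  They carry no
    geometry (|volume| far below one voxel) and are discarded.  Genuine small
    bodies and interior voids are at least voxel-sized and are kept.
    """
    import trimesh.graph

    comps = trimesh.graph.connected_components(
        mesh.to_trimesh().face_adjacency, nodes=np.arange(mesh.n_faces)
    )
    if len(comps) <= 1:
        return mesh
    tol = 0.01 * step**3
    keep = []
    for comp in comps:
        tri = mesh.vertices[mesh.faces[comp]]
        vol = abs(
            np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()
        ) / 6.0
        if vol >= tol:
            keep.append(comp)
        else:
            logger.debug("dropping degenerate shell of %d faces", len(comp))
    if len(keep) == len(comps):
        return mesh
    faces = np.concatenate(keep) if keep else np.arange(mesh.n_faces)
    return TriangleMesh(vertices=mesh.vertices, faces=mesh.faces[np.sort(faces)])


def merge_cells(cells, res: Optional[MeshResolution] = None) -> TriangleMesh:
    """Tessellate several cells into one mesh and report its component count.

    Disjoint cells stay separate connected components; touching or
    interpenetrating cells unify.  The count is logged and attached to the
    returned mesh as ``n_components``.
    """
    mesh = tessellate(cells, res)
    from .meshio import count_bodies

    mesh.n_components = count_bodies(mesh)
    logger.info("merged %d cell(s) into %d connected component(s)",
                1 if isinstance(cells, Morphology) else len(cells),
                mesh.n_components)
    return mesh
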