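"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
library: containment by axial projection (not signed distance fields),
boundary distance by 2D cross-section point-segment geometry, branch counts
by point-graph traversal, volumes by Monte-Carlo point-in-union sampling,
and a minimal VRML97 parser.
"""

from __future__ import annotations

import re

import numpy as np


# ---------------------------------------------------------------------------
# Frustum geometry by axial projection (independent of the SDF formulation)
# ---------------------------------------------------------------------------

def frustum_contains(f, pts: np.ndarray) -> np.ndarray:
    """Boolean containment test: project on the axis, compare the radial
    distance against the linearly interpolated radius."""
    pts = np.atleast_2d(pts)
    if f.is_sphere:
        return np.linalg.norm(pts - f.p0, axis=1) <= f.r0
    axis = f.p1 - f.p0
    length = np.linalg.norm(axis)
    u = axis / length
    a = (pts - f.p0) @ u
    radial = np.linalg.norm(pts - f.p0 - np.outer(a, u), axis=1)
    r_at = f.r0 + (f.r1 - f.r0) * np.clip(a / length, 0.0, 1.0)
    return (a >= 0.0) & (a <= length) & (radial <= r_at)


def _point_segment_distance_2d(p, a, b):
    """Distance from points p (N,2) to segment a-b in the plane."""
    p = np.atleast_2d(p)
    ab = np.asarray(b, float) - np.asarray(a, float)
    t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = np.asarray(a) + np.outer(t, ab)
    return np.linalg.norm(p - proj, axis=1)


def frustum_boundary_distance(f, pts: np.ndarray) -> np.ndarray:
    """Unsigned distance to the frustum boundary (lateral surface or caps),
    via the 2D (axial, radial) cross-section polyline."""
    pts = np.atleast_2d(pts)
    if f.is_sphere:
        return np.abs(np.linalg.norm(pts - f.p0, axis=1) - f.r0)
    axis = f.p1 - f.p0
    length = np.linalg.norm(axis)
    u = axis / length
    a = (pts - f.p0) @ u
    x = np.linalg.norm(pts - f.p0 - np.outer(a, u), axis=1)
    q = np.stack([a, x], axis=1)
    d = np.minimum.reduce([
        _point_segment_distance_2d(q, (0.0, 0.0), (0.0, f.r0)),      # near cap
        _point_segment_distance_2d(q, (0.0, f.r0), (length, f.r1)),  # lateral
        _point_segment_distance_2d(q, (length, f.r1), (length, 0.0)),  # far cap
    ])
    return d


def brute_force_assignment(frusta, centroids):
    """Reference triangle-to-segment mapping: least interior depth among
    containing frusta, else nearest boundary; ties by lowest
    (section_id, point_index)."""
    picks = []
    for c in centroids:
        best = None
        containing = []
        for f in frusta:
            inside = bool(frustum_contains(f, c[None])[0])
            dist = float(frustum_boundary_distance(f, c[None])[0])
            key = (dist, f.section_id, f.point_index)
            if inside:
                containing.append((key, f))
        if containing:
            _, f = min(containing)
        else:
            _, f = min(
                ((float(frustum_boundary_distance(f, c[None])[0]),
                  f.section_id, f.point_index), f)
                for f in frusta
            )
        picks.append((f.section_id, f.point_index))
    return picks


def union_contains(frusta, pts: np.ndarray) -> np.ndarray:
    inside = np.zeros(len(pts), dtype=bool)
    for f in frusta:
        inside |= frustum_contains(f, pts)
    return inside


def mc_union_volume(frusta, n_samples: int, seed: int = 0):
    """Monte-Carlo point-in-union volume estimate over the joint AABB."""
    los, his = zip(*(f.aabb() for f in frusta))
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    frac = union_contains(frusta, pts).mean()
    return float(frac * np.prod(hi - lo))


# ---------------------------------------------------------------------------
# Branch counting by point-graph traversal
# ---------------------------------------------------------------------------

def point_graph_counts(m):
    """(n_branch_points, n_branches, n_stems) from an undirected point graph.

    Nodes are (section_id, point_index) of neurite sections; edges join
    consecutive points and cross-section attachments.  In a tree rooted at
    the soma every maximal unbranched path ends at a leaf or a branch point,
    so n_branches = n_leaves + n_branch_points.
    """
    neurites = [s for s in m.sections if not s.is_soma]
    soma_ids = {s.id for s in m.sections if s.is_soma}
    nodes = set()
    adj = {}

    def add_edge(u, v):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    stem_roots = []
    for s in neurites:
        for i in range(len(s.points)):
            nodes.add((s.id, i))
        for i in range(len(s.points) - 1):
            add_edge((s.id, i), (s.id, i + 1))
        if s.parent_id in soma_ids or s.parent_id is None:
            stem_roots.append((s.id, 0))
        else:
            add_edge((s.parent_id, s.parent_point_index), (s.id, 0))

    n_stems = len(stem_roots)
    n_bp = 0
    n_leaves = 0
    for node in nodes:
        deg = len(adj.get(node, ()))
        is_root = node in stem_roots
        # rooted-tree child count: degree minus the parent edge
        children = deg if is_root else deg - 1
        if children >= 2:
            n_bp += 1
        if children == 0 and not is_root:
            n_leaves += 1
        if children == 0 and is_root:
            n_leaves += 1  # single-point stem is its own terminal
    return n_bp, n_leaves + n_bp, n_stems


# ---------------------------------------------------------------------------
# Mesh topology helpers (edge counting, not via trimesh)
# ---------------------------------------------------------------------------

def boundary_edge_count(faces: np.ndarray) -> int:
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
        axis=1,
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts != 2).sum())


def euler_characteristic(vertices: np.ndarray, faces: np.ndarray) -> int:
    used = np.unique(faces)
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
        axis=1,
    )
    n_edges = len(np.unique(edges, axis=0))
    return int(len(used) - n_edges + len(faces))


# ---------------------------------------------------------------------------
# Minimal VRML97 reference parser
# ---------------------------------------------------------------------------

def parse_wrl(text: str):
    """Extract vertices, faces, and per-face colors from a VRML97 file."""
    def block(name):
        m = re.search(name + r"\s*\[(.*?)\]", text, re.DOTALL)
        return m.group(1) if m else None

    pts = block(r"point")
    nums = [float(v) for v in re.findall(r"[-+0-9.eE]+", pts)]
    vertices = np.array(nums).reshape(-1, 3)

    ci = block(r"coordIndex")
    idx = [int(v) for v in re.findall(r"-?\d+", ci)]
    faces = []
    face = []
    for v in idx:
        if v == -1:
            faces.append(face)
            face = []
        else:
            face.append(v)
    faces = np.array(faces)

    colors = None
    cb = block(r"color\s*Color\s*\{\s*color")
    if cb is None:
        m = re.search(r"Color\s*\{\s*color\s*\[(.*?)\]", text, re.DOTALL)
        cb = m.group(1) if m else None
    if cb is not None:
        cnums = [float(v) for v in re.findall(r"[-+0-9.eE]+", cb)]
        colors = np.array(cnums).reshape(-1, 3)
    return vertices, faces, colors
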