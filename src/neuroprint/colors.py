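"""Map surface triangles back to skeleton segments and assign colors.

The tessellated surface does not remember which frustum generated which
triangle, so color-by-structure requires mapping each triangle back: a face
centroid is assigned to the frustum that contains it *by the least amount*
(smallest interior depth, i.e. distance to that frustum's boundary); a
centroid contained by no frustum goes to the frustum whose surface is
closest.  Ties break deterministically by lowest section id, then lowest
point index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import NeuroprintError
from .mesh import TriangleMesh
from .morphology import Morphology
from .surface import Frustum

logger = logging.getLogger(__name__)

CONTAINED = "contained"
NEAREST_SURFACE = "nearest_surface"


@dataclass
class SegmentAssignment:
    """Per-face mapping to (section_id, point_index) with the rule used."""

    section_id: np.ndarray  # (F,) int
    point_index: np.ndarray  # (F,) int
    method: np.ndarray  # (F,) str: 'contained' | 'nearest_surface'

    def __len__(self):
        return len(self.section_id)


def map_triangles_to_segments(
    mesh: TriangleMesh, frusta: Sequence[Frustum]
) -> SegmentAssignment:
    """Assign every face of ``mesh`` to one of the generating ``frusta``."""
    if not frusta:
        raise NeuroprintError("cannot map triangles: empty frusta list")
    order = sorted(
        range(len(frusta)), key=lambda i: (frusta[i].section_id, frusta[i].point_index)
    )
    frusta = [frusta[i] for i in order]

    centroids = mesh.face_centroids()
    n_faces = len(centroids)
    sdf = np.empty((n_faces, len(frusta)))
    for j, f in enumerate(frusta):
        sdf[:, j] = f.sdf(centroids)

    inside = sdf <= 0.0
    # interior depth (distance to the containing frustum's boundary); +inf
    # outside so argmin picks the least-deep containing frustum.  argmin
    # returns the first minimum, and frusta are pre-sorted by
    # (section_id, point_index), which implements the tie rule.
    depth = np.where(inside, -sdf, np.inf)
    contained_any = inside.any(axis=1)
    pick_contained = depth.argmin(axis=1)
    pick_nearest = sdf.argmin(axis=1)
    pick = np.where(contained_any, pick_contained, pick_nearest)

    sec = np.array([f.section_id for f in frusta], dtype=np.int64)
    pti = np.array([f.point_index for f in frusta], dtype=np.int64)
    method = np.where(contained_any, CONTAINED, NEAREST_SURFACE)
    return SegmentAssignment(
        section_id=sec[pick], point_index=pti[pick], method=method
    )


@dataclass
class ColorScheme:
    """How to color faces from their segment assignment.

    mode ``by_kind``: ``kind_map`` maps section kinds (plus the generic
    ``"dendrite"``) to RGB in [0, 1].  mode ``by_section_name``: ``name_map``
    maps section names.  mode ``by_scalar``: ``scalar`` maps section id (or
    ``(section_id, point_index)``) to a value, rendered by linear
    interpolation between ``stops`` over the observed value range.
    """

    mode: str = "by_kind"
    kind_map: Dict[str, tuple] = field(default_factory=dict)
    name_map: Dict[str, tuple] = field(default_factory=dict)
    scalar: Dict = field(default_factory=dict)
    stops: Sequence[tuple] = ((0.0, 0.0, 1.0), (1.0, 0.0, 0.0))
    default_color: tuple = (0.7, 0.7, 0.7)

    def __post_init__(self):
        if self.mode not in {"by_kind", "by_section_name", "by_scalar"}:
            raise NeuroprintError(f"unknown color scheme mode {self.mode!r}")
        for rgb in list(self.kind_map.values()) + list(self.name_map.values()) + [
            tuple(self.default_color)
        ] + [tuple(s) for s in self.stops]:
            arr = np.asarray(rgb, dtype=float)
            if arr.shape != (3,) or arr.min() < 0 or arr.max() > 1:
                raise NeuroprintError(f"invalid RGB triple {rgb!r}")


def _interp_stops(stops, t):
    """Piecewise-linear interpolation of color stops at t in [0, 1]."""
    stops = np.asarray(stops, dtype=float)
    if len(stops) == 1:
        return np.broadcast_to(stops[0], (len(t), 3)).copy()
    pos = t * (len(stops) - 1)
    i = np.clip(pos.astype(int), 0, len(stops) - 2)
    frac = (pos - i)[:, None]
    return stops[i] * (1 - frac) + stops[i + 1] * frac


def assign_colors(
    mesh: TriangleMesh,
    assignment: SegmentAssignment,
    scheme: ColorScheme,
    morphology: Optional[Morphology] = None,
) -> TriangleMesh:
    """Return a copy of ``mesh`` with one RGB color per face."""
    if len(assignment) != mesh.n_faces:
        raise NeuroprintError("assignment does not cover every face")
    out = mesh.copy()
    out.face_segment = np.stack(
        [assignment.section_id, assignment.point_index], axis=1
    )

    if scheme.mode in ("by_kind", "by_section_name"):
        if morphology is None:
            raise NeuroprintError(f"{scheme.mode} coloring needs the morphology")
        lookup = {}
        for s in morphology.sections:
            if scheme.mode == "by_kind":
                rgb = scheme.kind_map.get(s.kind)
                if rgb is None and s.kind in (
                    "basal_dendrite", "apical_dendrite", "custom"
                ):
                    rgb = scheme.kind_map.get("dendrite")
            else:
                rgb = scheme.name_map.get(s.name)
            lookup[s.id] = scheme.default_color if rgb is None else rgb
        out.face_color = np.array(
            [lookup.get(sid, scheme.default_color) for sid in assignment.section_id],
            dtype=float,
        )
        return out

    # by_scalar
    values = np.empty(mesh.n_faces)
    missing = set()
    for i, (sid, pix) in enumerate(
        zip(assignment.section_id, assignment.point_index)
    ):
        if (int(sid), int(pix)) in scheme.scalar:
            values[i] = scheme.scalar[(int(sid), int(pix))]
        elif int(sid) in scheme.scalar:
            values[i] = scheme.scalar[int(sid)]
        else:
            missing.add(int(sid))
    if missing:
        raise NeuroprintError(
            f"scalar value missing for mapped segment(s): {sorted(missing)}"
        )
    lo, hi = values.min(), values.max()
    t = np.zeros_like(values) if hi == lo else (values - lo) / (hi - lo)
    out.face_color = _interp_stops(scheme.stops, t)
    return out


def load_scalar_field(stream, morphology: Optional[Morphology] = None) -> dict:
    """Read a two-column text file of ``<section name or id> <value>`` pairs.

    Section names are resolved to ids when a morphology is given.
    """
    from .morphology import _open_text
    from pathlib import Path

    fh = _open_text(stream)
    close = isinstance(stream, (str, Path))
    try:
        field_map = {}
        by_name = (
            {s.name: s.id for s in morphology.sections} if morphology else {}
        )
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = line.split()
            if key in by_name:
                field_map[by_name[key]] = float(value)
            else:
                field_map[int(key)] = float(value)
        return field_map
    finally:
        if close:
            fh.close()
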