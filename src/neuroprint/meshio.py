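"""Mesh serialization (STL, VRML97) and print metadata.

Binary STL is the default interchange format (80-byte header, little-endian
uint32 triangle count, 50 bytes per triangle).  STL carries no color: writing
a colored mesh logs a warning and emits geometry only.  VRML97 (.wrl) carries
per-face color in an ``IndexedFaceSet`` with ``colorPerVertex FALSE``, which
is what full-color printing services consume.

STL and WRL files are unitless; the printed unit (millimeters after scaling)
travels in the JSON metadata sidecar (:class:`PrintableVersion`).
"""

from __future__ import annotations

import json
import logging
import struct
import uuid
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import IO, Optional, Union

import numpy as np

from .errors import MeshIOError, StatsError
from .mesh import TriangleMesh

logger = logging.getLogger(__name__)

_BINARY_HEADER = b"neuroprint binary STL" + b" " * 59


def _open_binary(stream, mode):
    if isinstance(stream, (str, Path)):
        return open(stream, mode), True
    return stream, False


def write_stl(
    mesh: TriangleMesh, stream: Union[str, Path, IO], binary: bool = True
) -> None:
    """Write a mesh as STL (binary by default, ASCII behind the flag).

    Normals are recomputed from the CCW winding.  STL cannot represent the
    mesh's per-face colors; they are dropped with a logged warning.
    """
    if mesh.n_faces == 0:
        raise MeshIOError("refusing to write an STL with no faces")
    if mesh.face_color is not None:
        logger.warning(
            "STL does not preserve color information; writing geometry only"
        )
    tri = mesh.triangles().astype("<f4")
    normals = mesh.face_normals().astype("<f4")

    if binary:
        fh, close = _open_binary(stream, "wb")
        try:
            fh.write(_BINARY_HEADER[:80])
            fh.write(struct.pack("<I", mesh.n_faces))
            record = np.zeros(
                mesh.n_faces,
                dtype=[("normal", "<f4", 3), ("verts", "<f4", (3, 3)),
                       ("attr", "<u2")],
            )
            record["normal"] = normals
            record["verts"] = tri
            fh.write(record.tobytes())
        finally:
            if close:
                fh.close()
        return

    lines = ["solid neuroprint"]
    for n, t in zip(normals, tri):
        lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
        lines.append("    outer loop")
        for v in t:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid neuroprint\n")
    text = "\n".join(lines)
    if isinstance(stream, (str, Path)):
        Path(stream).write_text(text)
    else:
        stream.write(text)


def read_stl(stream: Union[str, Path, IO]) -> TriangleMesh:
    """Read binary or ASCII STL; vertices deduplicated on exact float match."""
    if isinstance(stream, (str, Path)):
        data = Path(stream).read_bytes()
    else:
        data = stream.read()
        if isinstance(data, str):
            data = data.encode()
    if len(data) < 15:
        raise MeshIOError("not an STL file: too short")

    is_ascii = data.lstrip()[:5] == b"solid" and b"facet" in data[:1024]
    if is_ascii:
        tri = _parse_ascii_stl(data.decode("latin-1"))
    else:
        if len(data) < 84:
            raise MeshIOError(
                f"truncated binary STL: expected at least 84 bytes, got {len(data)}"
            )
        (count,) = struct.unpack("<I", data[80:84])
        expected = 84 + 50 * count
        if len(data) != expected:
            raise MeshIOError(
                f"truncated binary STL: expected {expected} bytes for "
                f"{count} triangles, got {len(data)}"
            )
        record = np.frombuffer(
            data, offset=84,
            dtype=[("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")],
        )
        tri = record["verts"].astype(float)

    flat = tri.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriangleMesh(vertices=uniq, faces=faces)


def _parse_ascii_stl(text: str) -> np.ndarray:
    verts = []
    for line in text.splitlines():
        parts = line.split()
        if parts and parts[0] == "vertex":
            if len(parts) != 4:
                raise MeshIOError(f"malformed ASCII STL vertex line: {line!r}")
            verts.append([float(v) for v in parts[1:]])
    if not verts or len(verts) % 3:
        raise MeshIOError("malformed ASCII STL: vertex count not a multiple of 3")
    return np.asarray(verts).reshape(-1, 3, 3)


# ---------------------------------------------------------------------------
# VRML97
# ---------------------------------------------------------------------------

def write_wrl(mesh: TriangleMesh, stream: Union[str, Path, IO]) -> None:
    """Write a VRML97 file with one IndexedFaceSet.

    When the mesh carries face colors, they are emitted per face
    (``colorPerVertex FALSE``), matching the per-triangle segment mapping.
    """
    if mesh.n_faces == 0:
        raise MeshIOError("refusing to write a WRL with no faces")
    parts = ["#VRML V2.0 utf8", "# written by neuroprint",
             "Shape {",
             "  appearance Appearance { material Material { } }",
             "  geometry IndexedFaceSet {",
             "    coord Coordinate {",
             "      point ["]
    parts.extend(
        f"        {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}," for v in mesh.vertices
    )
    parts.append("      ]")
    parts.append("    }")
    parts.append("    coordIndex [")
    parts.extend(f"      {f[0]}, {f[1]}, {f[2]}, -1," for f in mesh.faces)
    parts.append("    ]")
    if mesh.face_color is not None:
        parts.append("    colorPerVertex FALSE")
        parts.append("    color Color {")
        parts.append("      color [")
        parts.extend(
            f"        {c[0]:.6g} {c[1]:.6g} {c[2]:.6g},"
            for c in mesh.face_color
        )
        parts.append("      ]")
        parts.append("    }")
    parts.append("  }")
    parts.append("}")
    text = "\n".join(parts) + "\n"
    if isinstance(stream, (str, Path)):
        Path(stream).write_text(text)
    else:
        stream.write(text)


# ---------------------------------------------------------------------------
# Statistics and metadata
# ---------------------------------------------------------------------------

@dataclass
class MeshStats:
    """Measured properties of a triangle mesh (units as recorded)."""

    volume: Optional[float]
    surface_area: float
    bbox: tuple  # ((xmin, ymin, zmin), (xmax, ymax, zmax))
    n_components: int
    unit: str = "mm"


def signed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume by the divergence theorem (signed tetrahedron sum)."""
    tri = mesh.triangles()
    return float(
        np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    )


def surface_area(mesh: TriangleMesh) -> float:
    tri = mesh.triangles()
    return float(
        0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
    )


def count_bodies(mesh: TriangleMesh) -> int:
    """Number of solid bodies in a watertight, outward-oriented mesh.

    Face-connected shells with negative signed volume are interior voids
    (their normals point into the cavity) — e.g. pockets trapped between
    near-tangent dendrites — and belong to the enclosing body rather than
    counting as bodies of their own.
    """
    import trimesh.graph

    comps = trimesh.graph.connected_components(
        mesh.to_trimesh().face_adjacency, nodes=np.arange(mesh.n_faces)
    )
    n = sum(
        1
        for comp in comps
        if signed_volume(TriangleMesh(vertices=mesh.vertices, faces=mesh.faces[comp]))
        > 0
    )
    return max(n, 1)


def mesh_stats(
    mesh: TriangleMesh, unit: str = "mm", with_volume: bool = True
) -> MeshStats:
    """Volume, area, bounding box and component count of a mesh.

    Volume requires a watertight, consistently oriented mesh and raises
    :class:`StatsError` otherwise; pass ``with_volume=False`` to still get
    area, bbox and components.
    """
    tm = mesh.to_trimesh()
    volume = None
    if with_volume:
        if not (tm.is_watertight and tm.is_winding_consistent):
            raise StatsError(
                "volume is only defined for watertight, consistently "
                "oriented meshes (use with_volume=False for area/bbox)"
            )
        volume = signed_volume(mesh)
    import trimesh.graph

    comps = trimesh.graph.connected_components(
        tm.face_adjacency, nodes=np.arange(mesh.n_faces)
    )
    if tm.is_watertight and tm.is_winding_consistent and len(comps) > 1:
        comps = range(count_bodies(mesh))
    return MeshStats(
        volume=volume,
        surface_area=surface_area(mesh),
        bbox=(
            tuple(mesh.vertices.min(axis=0)),
            tuple(mesh.vertices.max(axis=0)),
        ),
        n_components=len(comps),
        unit=unit,
    )


@dataclass
class PrintableVersion:
    """Metadata record describing one printable rendition of a model.

    Mirrors the catalogue fields used for sharing printable neurons: name,
    comment, magnification (when known), printed volume and bounding box
    (cost drivers for commercial printing), generating algorithm, creator,
    date added, and a unique id.
    """

    name: str
    comment: str = ""
    magnification: Optional[float] = None
    printed_volume: Optional[float] = None
    bbox: Optional[tuple] = None
    algorithm: str = "sdf-marching-cubes"
    creator: str = "neuroprint"
    date_added: str = ""
    unique_id: str = ""

    def __post_init__(self):
        if self.magnification is not None and self.magnification <= 0:
            raise ValueError("magnification must be positive when known")
        if not self.unique_id:
            self.unique_id = uuid.uuid4().hex
        if not self.date_added:
            self.date_added = datetime.now(timezone.utc).isoformat()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PrintableVersion":
        payload = json.loads(text)
        if payload.get("bbox") is not None:
            payload["bbox"] = tuple(tuple(side) for side in payload["bbox"])
        return cls(**payload)
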