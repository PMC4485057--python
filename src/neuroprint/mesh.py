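"""Indexed triangle mesh container shared by the geometry and I/O modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class TriangleMesh:
    """Vertices + CCW-outward faces, with optional per-face annotations.

    ``face_segment`` maps each face to the (section_id, point_index) of the
    skeleton frustum it was generated from / assigned to; ``face_color`` holds
    one RGB triple in [0, 1] per face.
    """

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    face_segment: Optional[np.ndarray] = None  # (F, 2) int
    face_color: Optional[np.ndarray] = None  # (F, 3) float

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def face_normals(self) -> np.ndarray:
        """Unit normals from the CCW winding (zero for degenerate faces)."""
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(norm > 0, n / norm, 0.0)
        return unit

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            face_segment=None if self.face_segment is None else self.face_segment.copy(),
            face_color=None if self.face_color is None else self.face_color.copy(),
        )
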