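import numpy as np
import pytest

from _oracles import brute_force_assignment
from conftest import make_morph
from neuroprint.colors import (CONTAINED, NEAREST_SURFACE, ColorScheme,
                               assign_colors, map_triangles_to_segments)
from neuroprint.errors import NeuroprintError
from neuroprint.morphology import BASAL, SOMA
from neuroprint.surface import MeshResolution, skeleton_to_frusta, tessellate

RES = MeshResolution(spatial_step=0.25, refine_levels=1)


def split_cylinder():
    """One straight cable split into two sections at x=5."""
    return make_morph([
        (1, BASAL, [(0, 0, 0, 2), (5, 0, 0, 2)], None, None),
        (2, BASAL, [(10, 0, 0, 2)], 1, 1),
    ])


def soma_with_dendrite():
    return make_morph([
        (1, SOMA, [(0, 0, 0, 10)], None, None),
        (2, BASAL, [(5, 0, 0, 2), (15, 0, 0, 2)], 1, 0),
    ])


class TestMapTrianglesToSegments:
    def test_single_cylinder_total_assignment(self, cylinder_morph):
        frusta = skeleton_to_frusta(cylinder_morph)
        mesh = tessellate(cylinder_morph, RES)
        a = map_triangles_to_segments(mesh, frusta)
        assert len(a) == mesh.n_faces
        assert set(a.section_id) == {1}
        assert set(a.method) <= {CONTAINED, NEAREST_SURFACE}

    def test_split_cylinder_partitions_at_boundary(self):
        m = split_cylinder()
        frusta = skeleton_to_frusta(m)
        mesh = tessellate(m, RES)
        a = map_triangles_to_segments(mesh, frusta)
        cent = mesh.face_centroids()
        for c, sid in zip(cent, a.section_id):
            if c[0] < 5 - RES.spatial_step:
                assert sid == 1
            elif c[0] > 5 + RES.spatial_step:
                assert sid == 2

    @pytest.mark.parametrize("builder", [split_cylinder, soma_with_dendrite])
    def test_agrees_with_brute_force_oracle(self, builder):
        m = builder()
        frusta = skeleton_to_frusta(m)
        mesh = tessellate(m, MeshResolution(spatial_step=0.4, refine_levels=0))
        a = map_triangles_to_segments(mesh, frusta)
        oracle = brute_force_assignment(frusta, mesh.face_centroids())
        got = list(zip(a.section_id.tolist(), a.point_index.tolist()))
        agree = sum(1 for x, y in zip(got, oracle) if x == y)
        assert agree == mesh.n_faces

    def test_soma_far_cap_maps_to_soma(self):
        m = soma_with_dendrite()
        frusta = skeleton_to_frusta(m)
        mesh = tessellate(m, MeshResolution(spatial_step=0.5, refine_levels=1))
        a = map_triangles_to_segments(mesh, frusta)
        cent = mesh.face_centroids()
        far = cent[:, 0] < -4.0  # far hemisphere, outside any dendrite frustum
        assert far.any()
        assert set(a.section_id[far]) == {1}

    def test_nested_thin_frustum_wins_near_its_ends(self):
        # a thin long section passing axially through a fat short one
        m = make_morph([
            (1, BASAL, [(0, 0, 0, 6), (10, 0, 0, 6)], None, None),
            (2, BASAL, [(-6, 0, 0, 2), (16, 0, 0, 2)], None, None),
        ])
        frusta = skeleton_to_frusta(m)
        mesh = tessellate(m, MeshResolution(spatial_step=0.5, refine_levels=0))
        a = map_triangles_to_segments(mesh, frusta)
        cent = mesh.face_centroids()
        ends = (cent[:, 0] < -1.0) | (cent[:, 0] > 11.0)
        assert ends.any()
        assert set(a.section_id[ends]) == {2}
        oracle = brute_force_assignment(frusta, cent)
        got = list(zip(a.section_id.tolist(), a.point_index.tolist()))
        assert got == oracle

    def test_stable_under_face_reordering(self, cylinder_morph):
        frusta = skeleton_to_frusta(cylinder_morph)
        mesh = tessellate(cylinder_morph, RES)
        a = map_triangles_to_segments(mesh, frusta)
        perm = np.random.default_rng(0).permutation(mesh.n_faces)
        shuffled = mesh.copy()
        shuffled.faces = mesh.faces[perm]
        b = map_triangles_to_segments(shuffled, frusta)
        assert np.array_equal(a.section_id[perm], b.section_id)
        assert np.array_equal(a.point_index[perm], b.point_index)

    def test_empty_frusta_errors(self, cylinder_mesh_default):
        with pytest.raises(NeuroprintError, match="empty frusta"):
            map_triangles_to_segments(cylinder_mesh_default, [])


class TestAssignColors:
    def _mesh_and_assignment(self, m, res=RES):
        frusta = skeleton_to_frusta(m)
        mesh = tessellate(m, res)
        return mesh, map_triangles_to_segments(mesh, frusta)

    def test_by_kind_partitions_faces(self):
        m = soma_with_dendrite()
        mesh, a = self._mesh_and_assignment(
            m, MeshResolution(spatial_step=0.5, refine_levels=0))
        scheme = ColorScheme(mode="by_kind", kind_map={
            "soma": (1.0, 0.0, 0.0), "dendrite": (1.0, 1.0, 1.0)})
        out = assign_colors(mesh, a, scheme, m)
        red = np.all(out.face_color == (1, 0, 0), axis=1)
        white = np.all(out.face_color == (1, 1, 1), axis=1)
        assert (red | white).all()
        assert np.array_equal(red, a.section_id == 1)

    def test_constant_scalar_uniform_color(self, cylinder_morph):
        mesh, a = self._mesh_and_assignment(cylinder_morph)
        scheme = ColorScheme(mode="by_scalar", scalar={1: 3.14})
        out = assign_colors(mesh, a, scheme)
        assert (out.face_color == out.face_color[0]).all()

    def test_scalar_monotone_along_cable(self):
        # chain of 4 collinear sections with scalar = distance from origin
        m = make_morph([
            (1, BASAL, [(0, 0, 0, 2), (5, 0, 0, 2)], None, None),
            (2, BASAL, [(10, 0, 0, 2)], 1, 1),
            (3, BASAL, [(15, 0, 0, 2)], 2, 0),
            (4, BASAL, [(20, 0, 0, 2)], 3, 0),
        ])
        mesh, a = self._mesh_and_assignment(
            m, MeshResolution(spatial_step=0.5, refine_levels=0))
        scheme = ColorScheme(mode="by_scalar",
                             scalar={1: 0.0, 2: 1.0, 3: 2.0, 4: 3.0})
        out = assign_colors(mesh, a, scheme)
        x = mesh.face_centroids()[:, 0]
        red = out.face_color[:, 0]
        # segment boundaries land within one grid step, so compare binned
        # means along the axis rather than raw neighbors
        bins = np.floor((x - x.min()) / 0.5).astype(int)
        means = [red[bins == b].mean() for b in np.unique(bins)]
        assert (np.diff(means) >= -1e-12).all()

    def test_missing_scalar_names_segment(self, cylinder_morph):
        mesh, a = self._mesh_and_assignment(cylinder_morph)
        scheme = ColorScheme(mode="by_scalar", scalar={99: 1.0})
        with pytest.raises(NeuroprintError, match=r"\[1\]"):
            assign_colors(mesh, a, scheme)

    def test_invalid_rgb_rejected(self):
        with pytest.raises(NeuroprintError):
            ColorScheme(mode="by_kind", kind_map={"soma": (2.0, 0.0, 0.0)})
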