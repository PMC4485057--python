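import math

import numpy as np
import pytest

from _oracles import boundary_edge_count, euler_characteristic, mc_union_volume
from conftest import CYLINDER_VOLUME, SPHERE_VOLUME, make_morph
from neuroprint.edit import DiameterPolicy, apply_diameter_policy
from neuroprint.errors import MeshingError
from neuroprint.fixtures import TreeSpec, gen_cluster, gen_tree
from neuroprint.meshio import mesh_stats
from neuroprint.morphology import BASAL, SOMA
from neuroprint.surface import (Frustum, MeshResolution, merge_cells,
                                skeleton_to_frusta, tessellate)


class TestSkeletonToFrusta:
    def test_three_point_section(self):
        m = make_morph([(1, BASAL,
                         [(0, 0, 0, 2), (5, 0, 0, 2), (10, 0, 0, 2)],
                         None, None)])
        fr = skeleton_to_frusta(m)
        assert len(fr) == 2
        assert all(not f.is_sphere for f in fr)

    def test_spherical_soma(self, sphere_morph):
        fr = skeleton_to_frusta(sphere_morph)
        assert len(fr) == 1
        assert fr[0].is_sphere and fr[0].r0 == 5.0

    def test_counts_including_bridges(self, branched_cell):
        fr = skeleton_to_frusta(branched_cell)
        n_pair = sum(
            len(s.points) - 1 for s in branched_cell.sections
            if len(s.points) > 1
        )
        n_sphere = sum(
            1 for s in branched_cell.sections if len(s.points) == 1
        )
        n_bridge = sum(
            1 for s in branched_cell.sections
            if s.parent_id is not None and np.linalg.norm(
                s.points[0].xyz
                - branched_cell.section(s.parent_id)
                .points[s.parent_point_index].xyz) > 0
        )
        assert len(fr) == n_pair + n_sphere + n_bridge

    def test_provenance_recorded(self, cylinder_morph):
        fr = skeleton_to_frusta(cylinder_morph)
        assert fr[0].section_id == 1 and fr[0].point_index == 1

    def test_empty_section_errors(self):
        from neuroprint.morphology import Morphology, Section

        m = Morphology(sections=[Section(id=1, kind=BASAL, points=[])])
        with pytest.raises(MeshingError):
            skeleton_to_frusta(m)


class TestTessellate:
    def test_cylinder_volume_within_2pct(self, cylinder_mesh_default):
        v = mesh_stats(cylinder_mesh_default, unit="um").volume
        assert v == pytest.approx(CYLINDER_VOLUME, rel=0.02)

    def test_sphere_volume_within_2pct(self, sphere_mesh_default):
        v = mesh_stats(sphere_mesh_default, unit="um").volume
        assert v == pytest.approx(SPHERE_VOLUME, rel=0.02)

    def test_resolution_convergence(self, cylinder_morph):
        errs = []
        for step in (0.5, 0.25):
            mesh = tessellate(cylinder_morph, MeshResolution(spatial_step=step))
            v = mesh_stats(mesh, unit="um").volume
            errs.append(abs(v - CYLINDER_VOLUME))
        assert errs[1] < errs[0]

    @pytest.mark.parametrize("fixture",
                             ["cylinder_mesh_default", "sphere_mesh_default"])
    def test_watertight_closed_oriented(self, fixture, request):
        mesh = request.getfixturevalue(fixture)
        assert boundary_edge_count(mesh.faces) == 0
        tm = mesh.to_trimesh()
        assert tm.is_watertight and tm.is_winding_consistent
        chi = euler_characteristic(mesh.vertices, mesh.faces)
        assert chi % 2 == 0 and chi <= 2  # 2 - 2g with integer genus g >= 0

    def test_tree_mesh_watertight_single_component(self):
        m = gen_tree(TreeSpec(seed=9, n_bifurcations=4, n_stems=2))
        m = apply_diameter_policy(m, DiameterPolicy("fixed", 3.0))
        mesh = tessellate(m, MeshResolution(spatial_step=0.75, refine_levels=1))
        assert boundary_edge_count(mesh.faces) == 0
        assert mesh_stats(mesh, unit="um").n_components == 1

    def test_too_coarse_resolution_names_radius(self, cylinder_morph):
        with pytest.raises(MeshingError, match="radius 1"):
            tessellate(cylinder_morph, MeshResolution(spatial_step=2.0))

    def test_volume_monotone_under_floor(self):
        m = gen_tree(TreeSpec(seed=2, n_bifurcations=3, n_stems=2))
        res = MeshResolution(spatial_step=0.4, refine_levels=1)
        v0 = mesh_stats(tessellate(m, res), unit="um").volume
        fat = apply_diameter_policy(m, DiameterPolicy("floor", 2.5))
        v1 = mesh_stats(tessellate(fat, res), unit="um").volume
        assert v1 >= v0

    def test_rigid_rotation_invariance(self, cylinder_morph):
        v0 = mesh_stats(tessellate(cylinder_morph), unit="um").volume
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rot = cylinder_morph.copy()
        for s in rot.sections:
            for p in s.points:
                p.x, p.y, p.z = q @ p.xyz
        v1 = mesh_stats(tessellate(rot), unit="um").volume
        # grid sampling limits agreement across orientations
        assert v1 == pytest.approx(v0, rel=5e-3)


def crossing_cylinders():
    """Two r=1 cylinders crossing at right angles through the origin."""
    return make_morph([
        (1, BASAL, [(-5, 0, 0, 2), (5, 0, 0, 2)], None, None),
        (2, BASAL, [(0, -5, 0, 2), (0, 5, 0, 2)], None, None),
    ])


class TestUnionSemantics:
    def test_crossing_cylinders_unify(self):
        mesh = merge_cells([crossing_cylinders()])
        assert mesh.n_components == 1
        assert boundary_edge_count(mesh.faces) == 0
        v = mesh_stats(mesh, unit="um").volume
        assert v < 2 * CYLINDER_VOLUME  # strictly less than the plain sum
        frusta = skeleton_to_frusta(crossing_cylinders())
        oracle = mc_union_volume(frusta, n_samples=1_000_000, seed=3)
        assert v == pytest.approx(oracle, rel=0.02)

    def test_merge_single_cell_is_tessellate(self):
        cell = gen_tree(TreeSpec(seed=6, n_bifurcations=2, n_stems=1))
        res = MeshResolution(spatial_step=0.5, refine_levels=1)
        va = mesh_stats(merge_cells([cell], res), unit="um").volume
        vb = mesh_stats(tessellate(cell, res), unit="um").volume
        assert va == pytest.approx(vb, rel=1e-9)

    def test_distant_cells_stay_separate(self):
        cells = gen_cluster(1, convergence_point=(0, 0, 60), seed=1) + \
            gen_cluster(1, convergence_point=(800, 0, 60), seed=2,
                        center=(800, 0, 0))
        res = MeshResolution(refine_levels=1)
        mesh = merge_cells(cells, res)
        assert mesh.n_components == 2
        va = mesh_stats(tessellate(cells[0], res), unit="um").volume
        vb = mesh_stats(tessellate(cells[1], res), unit="um").volume
        vm = mesh_stats(mesh, unit="um").volume
        assert vm == pytest.approx(va + vb, rel=1e-3)

    def test_five_cell_cluster_single_component(self):
        cells = gen_cluster(5, seed=1)
        mesh = merge_cells(cells, MeshResolution(refine_levels=0))
        assert mesh.n_components == 1
        assert boundary_edge_count(mesh.faces) == 0
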