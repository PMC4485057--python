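import io

import numpy as np
import pytest

from _oracles import point_graph_counts
from conftest import BRANCHED_SWC, TOY_SWC, make_morph
from neuroprint.errors import ParseError, RepairError, StatsError
from neuroprint.fixtures import TreeSpec, gen_tree
from neuroprint.morphology import (AXON, BASAL, SOMA, branch_stats, read_asc,
                                   read_swc, remove_axon, repair_detached,
                                   write_swc)


class TestReadSWC:
    def test_minimal_file(self, toy_cell):
        assert len(toy_cell.sections) == 2
        assert sum(len(s.points) for s in toy_cell.sections) == 3
        assert toy_cell.detached_roots == []
        soma = toy_cell.soma_sections[0]
        assert soma.points[0].diameter == 10.0  # radius column doubled
        dend = toy_cell.neurite_sections[0]
        assert dend.kind == BASAL
        assert dend.parent_id == soma.id

    def test_detached_dendrite_is_flagged(self):
        swc = TOY_SWC + "4 3 50 50 0 1 -1\n5 3 60 50 0 1 4\n"
        m = read_swc(io.StringIO(swc))
        assert len(m.detached_roots) == 1
        sec = m.section(m.detached_roots[0])
        assert sec.parent_id is None
        assert sec.points[0].x == 50.0

    def test_missing_parent_id_is_flagged(self):
        swc = "1 1 0 0 0 5 -1\n2 3 10 0 0 1 99\n"
        m = read_swc(io.StringIO(swc))
        assert len(m.detached_roots) == 1

    def test_branch_split_into_sections(self, branched_cell):
        # soma, dendrite run, two daughters, axon
        assert len(branched_cell.sections) == 5
        kinds = sorted(s.kind for s in branched_cell.sections)
        assert kinds.count(AXON) == 1
        assert kinds.count(BASAL) == 3

    @pytest.mark.parametrize(
        "bad,match",
        [
            ("1 1 0 0 0 5 -1\n1 3 1 0 0 1 1\n", "duplicate"),
            ("1 1 0 0 0 five -1\n", "line 1"),
            ("1 1 0 0 0 5\n", "7 columns"),
            ("1 3 0 0 0 1 2\n2 3 1 0 0 1 1\n", "cyclic"),
        ],
    )
    def test_parse_errors(self, bad, match):
        with pytest.raises(ParseError, match=match):
            read_swc(io.StringIO(bad))

    def test_round_trip_is_exact(self, branched_cell):
        buf = io.StringIO()
        write_swc(branched_cell, buf)
        again = read_swc(io.StringIO(buf.getvalue()))
        assert len(again.sections) == len(branched_cell.sections)
        for a, b in zip(branched_cell.sections, again.sections):
            assert a.kind == b.kind
            assert np.allclose(a.xyz(), b.xyz())
            assert np.allclose(a.diameters(), b.diameters())
        buf2 = io.StringIO()
        write_swc(again, buf2)
        assert buf.getvalue() == buf2.getvalue()


ASC_TOY = """
; encoded by hand
("CellBody" (CellBody)
  (5 0 0 2) (0 5 0 2) (-5 0 0 2) (0 -5 0 2))
( (Dendrite)
  ( 10 0 0 2)
  ( 20 0 0 2)
  ( ( 30 5 0 1.5) ( 40 8 0 1.5)
  | ( 30 -5 0 1.5) )
)
"""

SWC_TOY_EQUIVALENT = """
1 1 0 0 0 5 -1
2 3 10 0 0 1 1
3 3 20 0 0 1 2
4 3 30 5 0 0.75 3
5 3 40 8 0 0.75 4
6 3 30 -5 0 0.75 3
"""


class TestReadASC:
    def test_cellbody_contour_and_dendrite(self):
        m = read_asc(io.StringIO(ASC_TOY))
        assert m.soma_outline is not None
        assert len(m.soma_outline) == 4
        assert len([s for s in m.neurite_sections]) == 3

    def test_bar_separator_makes_siblings(self):
        m = read_asc(io.StringIO(ASC_TOY))
        root = next(s for s in m.neurite_sections if s.points[0].x == 10.0)
        kids = m.children_of(root.id)
        assert len(kids) == 2
        assert all(k.parent_point_index == len(root.points) - 1 for k in kids)

    def test_asc_and_swc_encodings_agree(self):
        sa = branch_stats(read_asc(io.StringIO(ASC_TOY)))
        sb = branch_stats(read_swc(io.StringIO(SWC_TOY_EQUIVALENT)))
        assert sa == sb

    def test_unbalanced_parens(self):
        with pytest.raises(ParseError, match="unbalanced"):
            read_asc(io.StringIO("( (Dendrite) (1 2 3 4)"))

    def test_unknown_block_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            m = read_asc(io.StringIO('(ImageCoords)\n' + ASC_TOY))
        assert "skipping unknown" in caplog.text
        assert len(m.neurite_sections) == 3


class TestRepairDetached:
    def test_prepends_soma_centroid_at_constant_diameter(self):
        swc = "1 1 0 0 0 5 -1\n2 3 10 0 0 1 -1\n3 3 20 0 0 1 2\n"
        m = read_swc(io.StringIO(swc))
        r = repair_detached(m)
        sec = r.neurite_sections[0]
        assert np.allclose(sec.points[0].xyz, [0, 0, 0])
        assert sec.points[0].diameter == 2.0  # first measured point's diameter
        # measured coordinates never move
        assert np.allclose(sec.points[1].xyz, [10, 0, 0])
        assert r.detached_roots == []

    def test_no_detached_roots_is_identity(self, toy_cell):
        assert repair_detached(toy_cell) is toy_cell

    def test_two_detached_roots_single_component(self):
        swc = ("1 1 0 0 0 5 -1\n"
               "2 3 10 0 0 1 -1\n"
               "3 3 0 12 0 1 -1\n")
        m = read_swc(io.StringIO(swc))
        assert m.n_components() == 3
        r = repair_detached(m)
        assert r.n_components() == 1

    def test_requires_soma(self):
        swc = "1 3 10 0 0 1 -1\n"
        with pytest.raises(RepairError):
            repair_detached(read_swc(io.StringIO(swc)))


class TestRemoveAxon:
    def test_axon_removed_dendrites_kept(self, branched_cell):
        out = remove_axon(branched_cell)
        assert all(s.kind != AXON for s in out.sections)
        assert len(out.soma_sections) == 1
        assert len(out.neurite_sections) == 3

    def test_axonal_subtree_removed(self):
        swc = ("1 1 0 0 0 5 -1\n"
               "2 2 10 0 0 1 1\n"
               "3 2 20 5 0 1 2\n"
               "4 2 20 -5 0 1 2\n")
        out = remove_axon(read_swc(io.StringIO(swc)))
        assert out.neurite_sections == []

    def test_no_axon_is_identity(self, toy_cell):
        assert remove_axon(toy_cell) is toy_cell


class TestBranchStats:
    def test_single_unbranched_dendrite(self, toy_cell):
        s = branch_stats(toy_cell)
        assert (s.n_branch_points, s.n_branches, s.n_stems) == (0, 1, 1)
        assert s.total_length == pytest.approx(10.0)
        assert s.n_points == 2

    @pytest.mark.parametrize("b,stems", [(0, 1), (1, 1), (4, 2), (7, 2), (5, 3)])
    def test_binary_tree_identity_against_point_graph(self, b, stems):
        m = gen_tree(TreeSpec(seed=11, n_bifurcations=b, n_stems=stems))
        s = branch_stats(m)
        assert s.n_branch_points == b
        assert s.n_stems == stems
        assert s.n_branches == 2 * b + stems
        assert (s.n_branch_points, s.n_branches, s.n_stems) == \
            point_graph_counts(m)

    def test_empty_morphology_errors(self):
        from neuroprint.morphology import Morphology

        with pytest.raises(StatsError):
            branch_stats(Morphology())

    def test_total_length_rigid_invariance(self):
        m = gen_tree(TreeSpec(seed=3, n_bifurcations=5, n_stems=2))
        base = branch_stats(m).total_length
        rng = np.random.default_rng(0)
        # random rotation via QR decomposition + a translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-50, 50, 3)
        for sec in m.sections:
            for p in sec.points:
                p.x, p.y, p.z = q @ p.xyz + t
        assert branch_stats(m).total_length == pytest.approx(base, rel=1e-9)


class TestWriteSWC:
    def test_round_trip_preserves_stats(self, branched_cell):
        buf = io.StringIO()
        write_swc(branched_cell, buf)
        assert branch_stats(read_swc(io.StringIO(buf.getvalue()))) == \
            branch_stats(branched_cell)

    def test_output_has_no_detached_roots_and_counts_nodes(self, branched_cell):
        buf = io.StringIO()
        write_swc(branched_cell, buf)
        text = buf.getvalue()
        again = read_swc(io.StringIO(text))
        assert again.detached_roots == []
        n_nodes = sum(1 for l in text.splitlines() if not l.startswith("#"))
        assert n_nodes == sum(len(s.points) for s in branched_cell.sections)

    def test_outline_soma_falls_back_to_sphere(self, caplog):
        m = read_asc(io.StringIO(ASC_TOY))
        m.sections = [s for s in m.sections if not s.is_soma]  # outline only
        for s in m.sections:
            if s.parent_id is not None and s.parent_id not in {x.id for x in m.sections}:
                s.parent_id = None
        buf = io.StringIO()
        with caplog.at_level("WARNING"):
            write_swc(m, buf)
        assert "equivalent sphere" in caplog.text
        again = read_swc(io.StringIO(buf.getvalue()))
        assert len(again.soma_sections) == 1
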