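"""Neuronal morphology containers and SWC / Neurolucida ASC readers.

A morphology is a tree of *sections*: unbranched polylines of 3D points with
per-point diameters, in microns.  The soma is represented either by its own
section(s) (a sphere for a single tracing point, a frustum chain otherwise) or
by a traced outline contour (Neurolucida ``CellBody`` blocks).

Conventions
-----------
* Section points store only the section's own tracing nodes; attachment to the
  parent is kept as ``(parent_id, parent_point_index)``.  The surface generator
  bridges the physical gap with an explicit connecting frustum.
* All morphometric counts (branch points, branches, stems, total length,
  point count) cover the neurite tree only; the soma is excluded.  With this
  convention a cell encoded as SWC (soma node) and as ASC (soma contour)
  yields identical statistics.
"""

from __future__ import annotations

import copy as _copy
import logging
import math
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import numpy as np

from .errors import NeuroprintError, ParseError, RepairError, StatsError

logger = logging.getLogger(__name__)

# Section kinds.  SWC type codes 1-4 map onto the first four; anything >= 5 is
# preserved as ``custom`` with its original code and is treated like a dendrite
# downstream.
SOMA = "soma"
AXON = "axon"
BASAL = "basal_dendrite"
APICAL = "apical_dendrite"
CUSTOM = "custom"

_SWC_CODE_TO_KIND = {1: SOMA, 2: AXON, 3: BASAL, 4: APICAL}
_KIND_TO_SWC_CODE = {SOMA: 1, AXON: 2, BASAL: 3, APICAL: 4}


@dataclass
class MorphPoint:
    """A single tracing point: position (µm) and diameter (µm)."""

    x: float
    y: float
    z: float
    diameter: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass
class Section:
    """An unbranched run of tracing points of one kind."""

    id: int
    kind: str
    points: list
    parent_id: Optional[int] = None
    parent_point_index: Optional[int] = None
    name: str = ""
    swc_code: Optional[int] = None  # original SWC type code for custom kinds

    def xyz(self) -> np.ndarray:
        return np.array([[p.x, p.y, p.z] for p in self.points], dtype=float)

    def diameters(self) -> np.ndarray:
        return np.array([p.diameter for p in self.points], dtype=float)

    @property
    def is_soma(self) -> bool:
        return self.kind == SOMA

    def length(self) -> float:
        """Path length along this section's own points."""
        if len(self.points) < 2:
            return 0.0
        xyz = self.xyz()
        return float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())


@dataclass
class Morphology:
    """A reconstructed cell: sections plus optional soma outline."""

    sections: list = field(default_factory=list)
    soma_outline: Optional[np.ndarray] = None
    source_format: str = "swc"
    detached_roots: list = field(default_factory=list)

    # -- structural helpers -------------------------------------------------

    def section(self, sec_id: int) -> Section:
        for s in self.sections:
            if s.id == sec_id:
                return s
        raise KeyError(f"no section with id {sec_id}")

    def children_of(self, sec_id: int) -> list:
        return [s for s in self.sections if s.parent_id == sec_id]

    @property
    def soma_sections(self) -> list:
        return [s for s in self.sections if s.is_soma]

    @property
    def neurite_sections(self) -> list:
        return [s for s in self.sections if not s.is_soma]

    @property
    def has_soma(self) -> bool:
        return bool(self.soma_sections) or self.soma_outline is not None

    def copy(self) -> "Morphology":
        return _copy.deepcopy(self)

    def soma_center(self) -> np.ndarray:
        """Volume-weighted center of mass of the soma.

        Single-point soma sections are spheres; multi-point sections are
        frustum chains with analytic per-frustum centroids.  A bare outline
        contour falls back to the area centroid of the polygon.
        """
        from .edit import soma_center_of_mass  # local import avoids a cycle

        return soma_center_of_mass(self)

    def n_components(self) -> int:
        """Connected components of the section graph (soma included)."""
        ids = {s.id for s in self.sections}
        parent = {}
        for s in self.sections:
            parent[s.id] = s.parent_id if s.parent_id in ids else None

        def find_root(i):
            seen = set()
            while parent[i] is not None:
                if i in seen:
                    raise NeuroprintError("section graph contains a cycle")
                seen.add(i)
                i = parent[i]
            return i

        return len({find_root(i) for i in ids})


@dataclass
class MorphStats:
    """Morphometric summary of the neurite tree (soma excluded)."""

    n_branch_points: int
    n_branches: int
    n_stems: int
    total_length: float
    n_points: int


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def _open_text(stream: Union[str, Path, IO]) -> IO:
    if isinstance(stream, (str, Path)):
        return open(stream, "r")
    return stream


def read_swc(stream: Union[str, Path, IO]) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    One section is created per unbranched run of same-type nodes.  The SWC
    radius column is doubled into point diameters.  Neurite nodes with parent
    ``-1`` (or a parent id absent from the file) start sections flagged in
    ``detached_roots``.
    """
    fh = _open_text(stream)
    close = isinstance(stream, (str, Path))
    try:
        nodes = {}
        order = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ParseError(
                    f"expected 7 columns, found {len(fields)}", line=lineno
                )
            try:
                nid = int(fields[0])
                code = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"non-numeric field ({exc})", line=lineno) from None
            if nid in nodes:
                raise ParseError(f"duplicate node id {nid}", line=lineno)
            nodes[nid] = (code, x, y, z, r, parent)
            order.append(nid)
    finally:
        if close:
            fh.close()

    if not nodes:
        raise ParseError("empty SWC file")

    # cycle detection on the parent chain
    state = {}
    for nid in order:
        path = []
        cur = nid
        while cur in nodes and state.get(cur) is None:
            state[cur] = "visiting"
            path.append(cur)
            cur = nodes[cur][5]
            if state.get(cur) == "visiting":
                raise ParseError(f"cyclic parent chain involving node {cur}")
        for p in path:
            state[p] = "done"

    children = {nid: [] for nid in nodes}
    roots = []
    missing_parent = set()
    for nid in order:
        parent = nodes[nid][5]
        if parent == -1:
            roots.append(nid)
        elif parent not in nodes:
            missing_parent.add(nid)
            roots.append(nid)
        else:
            children[parent].append(nid)

    def kind_of(nid):
        code = nodes[nid][0]
        return _SWC_CODE_TO_KIND.get(code, CUSTOM)

    def point_of(nid):
        _, x, y, z, r, _ = nodes[nid]
        return MorphPoint(x, y, z, 2.0 * r)

    morph = Morphology(source_format="swc")
    node_loc = {}  # node id -> (section id, point index)
    next_sec = [1]
    kind_counts = {}

    def new_section(start, parent_sec, parent_idx, flag_detached):
        kind = kind_of(start)
        run = [start]
        cur = start
        while True:
            kids = children[cur]
            if len(kids) != 1:
                break
            nxt = kids[0]
            if kind_of(nxt) != kind:
                break
            run.append(nxt)
            cur = nxt
        code = nodes[start][0]
        idx = kind_counts.get(kind, 0)
        kind_counts[kind] = idx + 1
        sec = Section(
            id=next_sec[0],
            kind=kind,
            points=[point_of(n) for n in run],
            parent_id=parent_sec,
            parent_point_index=parent_idx,
            name=f"{kind}[{idx}]",
            swc_code=code if kind == CUSTOM else None,
        )
        next_sec[0] += 1
        morph.sections.append(sec)
        for i, n in enumerate(run):
            node_loc[n] = (sec.id, i)
        if flag_detached:
            morph.detached_roots.append(sec.id)
        # recurse into children of the run's last node, and into side branches
        for n in run:
            for kid in children[n]:
                if kid in node_loc:  # absorbed into this run already
                    continue
                new_section(kid, sec.id, node_loc[n][1], False)

    for root in roots:
        detached = kind_of(root) != SOMA and (
            root in missing_parent or nodes[root][5] == -1
        )
        # a soma root is never detached; a neurite root is
        if kind_of(root) == SOMA:
            detached = False
        new_section(root, None, None, detached)

    return morph


def write_swc(m: Morphology, stream: Union[str, Path, IO]) -> None:
    """Write a morphology as standard 7-column SWC.

    Node ids are contiguous from 1; diameters are halved back to radii.  A
    soma represented only by an outline contour is written as an equivalent
    sphere at the contour centroid (with a logged warning).
    """
    m = m.copy()
    if not m.soma_sections and m.soma_outline is not None:
        logger.warning(
            "soma outline cannot be represented in SWC; writing an "
            "equivalent sphere at the contour centroid"
        )
        _materialize_outline_soma(m)

    lines = ["# generated by neuroprint"]
    next_id = [1]
    sec_node_ids = {}  # section id -> list of node ids

    def emit(sec: Section):
        code = (
            sec.swc_code
            if sec.kind == CUSTOM and sec.swc_code is not None
            else _KIND_TO_SWC_CODE.get(sec.kind, 5)
        )
        ids = []
        for i, p in enumerate(sec.points):
            nid = next_id[0]
            next_id[0] += 1
            if i > 0:
                parent = ids[-1]
            elif sec.parent_id is not None and sec.parent_id in sec_node_ids:
                parent = sec_node_ids[sec.parent_id][sec.parent_point_index]
            else:
                parent = -1
            lines.append(
                f"{nid} {code} {p.x:.6f} {p.y:.6f} {p.z:.6f} "
                f"{0.5 * p.diameter:.6f} {parent}"
            )
            ids.append(nid)
        sec_node_ids[sec.id] = ids

    # parents before children
    emitted = set()
    pending = list(m.sections)
    while pending:
        progressed = False
        for sec in list(pending):
            if sec.parent_id is None or sec.parent_id in emitted:
                emit(sec)
                emitted.add(sec.id)
                pending.remove(sec)
                progressed = True
        if not progressed:
            raise NeuroprintError("section graph contains a cycle or dangling parent")

    text = "\n".join(lines) + "\n"
    if isinstance(stream, (str, Path)):
        Path(stream).write_text(text)
    else:
        stream.write(text)


def _materialize_outline_soma(m: Morphology) -> Section:
    """Replace/augment an outline-only soma with an equivalent sphere section."""
    outline = np.asarray(m.soma_outline, dtype=float)
    centroid = outline.mean(axis=0)
    # area-equivalent radius of the contour polygon (projected on its best
    # plane; for the restricted dialect contours are planar)
    rel = outline - centroid
    # principal plane via SVD
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    uv = rel @ vt[:2].T
    x, y = uv[:, 0], uv[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    radius = math.sqrt(area / math.pi) if area > 0 else float(np.linalg.norm(rel, axis=1).mean())
    sec = Section(
        id=max((s.id for s in m.sections), default=0) + 1,
        kind=SOMA,
        points=[MorphPoint(*centroid, 2.0 * radius)],
        name="soma[contour]",
    )
    m.sections.insert(0, sec)
    # reattach parentless neurites to the new soma
    for s in m.sections:
        if not s.is_soma and s.parent_id is None and s.id not in m.detached_roots:
            s.parent_id = sec.id
            s.parent_point_index = 0
    return sec


# ---------------------------------------------------------------------------
# Neurolucida ASC (restricted dialect)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<comment>;[^\n]*)
      | (?P<open>\()
      | (?P<close>\))
      | (?P<bar>\|)
      | (?P<string>"[^"]*")
      | (?P<atom>[^\s()|;]+)
    )""",
    re.VERBOSE,
)


def _tokenize_asc(text: str):
    pos = 0
    tokens = []
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            break
        pos = match.end()
        if match.lastgroup == "comment" or match.group().strip() == "":
            continue
        kind = match.lastgroup
        if kind is None:
            continue
        tokens.append((kind, match.group(kind)))
    return tokens


def _parse_sexpr(tokens, i):
    """Parse one parenthesized expression starting at tokens[i] == '('."""
    assert tokens[i][0] == "open"
    items = []
    i += 1
    while i < len(tokens):
        kind, value = tokens[i]
        if kind == "close":
            return items, i + 1
        if kind == "open":
            sub, i = _parse_sexpr(tokens, i)
            items.append(sub)
        else:
            items.append(value)
            i += 1
    raise ParseError("unbalanced parentheses in ASC input")


_ASC_TREE_HEADERS = {
    "axon": AXON,
    "dendrite": BASAL,
    "apical": APICAL,
    "cellbody": SOMA,
}


def _is_point(item) -> bool:
    if not isinstance(item, list) or len(item) != 4:
        return False
    try:
        [float(v) for v in item]
        return True
    except (TypeError, ValueError):
        return False


def read_asc(stream: Union[str, Path, IO]) -> Morphology:
    """Read a restricted Neurolucida ASC file.

    Supported top-level blocks: a ``CellBody`` contour and neurite trees
    headed by ``Axon`` / ``Dendrite`` / ``Apical``, made of ``(x y z d)``
    points with ``|``-separated daughter branches.  Unknown top-level blocks
    are skipped with a logged warning.
    """
    fh = _open_text(stream)
    close = isinstance(stream, (str, Path))
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()

    tokens = _tokenize_asc(text)
    blocks = []
    i = 0
    while i < len(tokens):
        kind, value = tokens[i]
        if kind == "open":
            block, i = _parse_sexpr(tokens, i)
            blocks.append(block)
        elif kind == "close":
            raise ParseError("unbalanced parentheses in ASC input")
        else:
            i += 1  # stray atom between blocks: ignore

    morph = Morphology(source_format="asc")
    next_id = [1]
    kind_counts = {}

    def block_header(block) -> Optional[str]:
        # headers appear as a bare word/string or wrapped: ( (Dendrite) ... )
        for item in block:
            words = []
            if isinstance(item, str):
                words = [item]
            elif isinstance(item, list) and all(isinstance(w, str) for w in item):
                words = item
            for w in words:
                word = w.strip('"').lower()
                if word in _ASC_TREE_HEADERS:
                    return word
        return None

    def collect_points(items):
        return [
            MorphPoint(float(a), float(b), float(c), float(d))
            for a, b, c, d in (it for it in items if _is_point(it))
        ]

    def build_tree(items, kind, parent_id, parent_idx):
        """Build sections from a list of items: leading points then an
        optional branch group containing |-separated daughters."""
        pts = []
        branch_group = None
        for item in items:
            if _is_point(item):
                pts.append(MorphPoint(*[float(v) for v in item]))
            elif isinstance(item, list) and _contains_bar_or_points(item):
                branch_group = item
            # markers/colors/other annotation lists are ignored
        if not pts:
            raise ParseError("neurite tree with no points")
        idx = kind_counts.get(kind, 0)
        kind_counts[kind] = idx + 1
        sec = Section(
            id=next_id[0],
            kind=kind,
            points=pts,
            parent_id=parent_id,
            parent_point_index=parent_idx,
            name=f"{kind}[{idx}]",
        )
        next_id[0] += 1
        morph.sections.append(sec)
        if branch_group is not None:
            for daughter in _split_on_bars(branch_group):
                if daughter:
                    build_tree(daughter, kind, sec.id, len(pts) - 1)
        return sec

    soma_sec_id = None
    for block in blocks:
        header = block_header(block)
        if header == "cellbody":
            outline = collect_points(block)
            if not outline:
                raise ParseError("CellBody block with no contour points")
            morph.soma_outline = np.array([[p.x, p.y, p.z] for p in outline])
            _materialize_outline_soma(morph)
            soma_sec_id = morph.soma_sections[0].id
            next_id[0] = max(next_id[0], soma_sec_id + 1)
        elif header in ("axon", "dendrite", "apical"):
            items = [it for it in block if not (isinstance(it, str) and it.strip('"').lower() == header)]
            build_tree(items, _ASC_TREE_HEADERS[header], None, None)
        else:
            label = next((it for it in block if isinstance(it, str)), "<anonymous>")
            logger.warning("skipping unknown ASC top-level block %r", label)

    # attach parentless neurite roots to the soma, if one exists
    if soma_sec_id is not None:
        for s in morph.sections:
            if not s.is_soma and s.parent_id is None:
                s.parent_id = soma_sec_id
                s.parent_point_index = 0
    return morph


def _contains_bar_or_points(item) -> bool:
    """A branch group is a list holding points/sublists, possibly with '|'."""
    if not isinstance(item, list) or _is_point(item):
        return False
    return any(
        it == "|" or _is_point(it) or (isinstance(it, list) and _contains_bar_or_points(it))
        for it in item
    )


def _split_on_bars(items):
    groups = [[]]
    for it in items:
        if it == "|":
            groups.append([])
        else:
            groups[-1].append(it)
    return groups


# ---------------------------------------------------------------------------
# Repair and edit operations
# ---------------------------------------------------------------------------

def repair_detached(m: Morphology) -> Morphology:
    """Reattach detached neurite roots to the soma.

    Each detached root gains a prepended point at the soma's volume centroid,
    at the root's first-point diameter; measured coordinates are never moved.
    Returns a new morphology with ``detached_roots`` empty.
    """
    if not m.detached_roots:
        return m
    if not m.has_soma:
        raise RepairError("cannot reattach detached roots: morphology has no soma")
    m = m.copy()
    if not m.soma_sections:
        _materialize_outline_soma(m)
    centroid = m.soma_center()
    soma = m.soma_sections[0]
    for sec_id in m.detached_roots:
        sec = m.section(sec_id)
        first = sec.points[0]
        sec.points.insert(0, MorphPoint(*centroid, first.diameter))
        sec.parent_id = soma.id
        sec.parent_point_index = int(
            np.argmin(np.linalg.norm(soma.xyz() - centroid, axis=1))
        )
    m.detached_roots = []
    return m


def remove_axon(m: Morphology) -> Morphology:
    """Drop all axonal sections and their descendants."""
    axon_ids = {s.id for s in m.sections if s.kind == AXON}
    if not axon_ids:
        return m
    removed = set(axon_ids)
    changed = True
    while changed:
        changed = False
        for s in m.sections:
            if s.id not in removed and s.parent_id in removed:
                removed.add(s.id)
                changed = True
    out = m.copy()
    out.sections = [s for s in out.sections if s.id not in removed]
    out.detached_roots = [i for i in out.detached_roots if i not in removed]
    return out


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def branch_stats(m: Morphology) -> MorphStats:
    """Morphometrics over the neurite tree.

    Branch points are non-soma topological nodes with >= 2 outgoing edges;
    stems are neurite sections attached directly to the soma (or parentless
    roots); branches are maximal unbranched paths between soma, branch points
    and terminations; total length sums 3D point-to-point distances between
    neurite points, including cross-section attachment edges between neurite
    sections (soma-to-neurite gaps are excluded).
    """
    neurites = m.neurite_sections
    if not m.sections:
        raise StatsError("empty morphology")

    soma_ids = {s.id for s in m.soma_sections}
    neurite_ids = {s.id for s in neurites}

    n_points = sum(len(s.points) for s in neurites)
    total_length = 0.0
    for s in neurites:
        total_length += s.length()
        if s.parent_id in neurite_ids:
            parent = m.section(s.parent_id)
            attach = parent.points[s.parent_point_index].xyz
            total_length += float(np.linalg.norm(s.points[0].xyz - attach))

    stems = [
        s
        for s in neurites
        if s.parent_id in soma_ids
        or s.parent_id is None
        or s.parent_id not in neurite_ids | soma_ids
    ]
    n_stems = len(stems)

    # children attached at each (section, point index) of a neurite section
    attach_children = {}
    for s in neurites:
        if s.parent_id in neurite_ids:
            key = (s.parent_id, s.parent_point_index)
            attach_children.setdefault(key, []).append(s.id)

    n_branch_points = 0
    n_branches = n_stems
    for s in neurites:
        last = len(s.points) - 1
        for (sec_id, idx), kids in attach_children.items():
            if sec_id != s.id:
                continue
            outgoing = len(kids) + (1 if idx < last else 0)
            if outgoing >= 2:
                n_branch_points += 1
                n_branches += outgoing

    return MorphStats(
        n_branch_points=n_branch_points,
        n_branches=n_branches,
        n_stems=n_stems,
        total_length=total_length,
        n_points=n_points,
    )
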