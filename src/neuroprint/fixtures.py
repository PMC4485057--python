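"""Synthetic morphologies with analytically known ground truth.

These generators stand in for repository tracings so that every pipeline
stage is testable without downloads: random trees with an exact bifurcation
count, trees with injected tracing defects (detached roots, zero diameters,
slice amputation), and multi-cell clusters whose apical dendrites converge
on a shared point — a miniature analogue of mitral cells converging on one
glomerulus — guaranteeing mesh overlap by construction.

All geometry is drawn from one seeded NumPy generator, so a given spec
reproduces byte-identical SWC output across platforms.  The trees guarantee
topological and geometric ground truth (every branch point is a
bifurcation), not biological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import NeuroprintError
from .morphology import BASAL, APICAL, SOMA, MorphPoint, Morphology, Section


@dataclass
class TreeSpec:
    """Parameters of a synthetic dendritic tree.

    Segment lengths (µm) are uniform in ``segment_length_range``; each child
    section's diameter is the parent's times ``taper``.  ``planarity``
    ``"planar"`` keeps the whole tree in the z=0 plane (a slice-like
    morphology); ``"3d"`` grows in all directions.
    """

    seed: int = 0
    n_bifurcations: int = 7
    n_stems: int = 2
    segment_length_range: Tuple[float, float] = (8.0, 15.0)
    taper: float = 0.9
    soma_diameter: float = 12.0
    planarity: str = "3d"
    stem_diameter: float = 2.0
    points_per_section: int = 3

    def __post_init__(self):
        if self.n_stems < 1 and self.n_bifurcations > 0:
            raise NeuroprintError("cannot place bifurcations on a tree with no stems")
        if not (0 < self.taper <= 1):
            raise NeuroprintError("taper must be in (0, 1]")
        if min(self.segment_length_range) <= 0 or self.soma_diameter <= 0 \
                or self.stem_diameter <= 0:
            raise NeuroprintError("lengths and diameters must be positive")
        if self.planarity not in ("planar", "3d"):
            raise NeuroprintError(f"unknown planarity {self.planarity!r}")
        if self.points_per_section < 2:
            raise NeuroprintError("sections need at least 2 points")


@dataclass
class TreeGroundTruth:
    """Totals recorded while drawing a synthetic tree."""

    total_length: float  # neurite point-to-point length, µm
    frustum_volume: float  # summed analytic frustum volume incl. soma bridges
    n_bifurcations: int
    n_stems: int


def _frustum_vol(h: float, r0: float, r1: float) -> float:
    return math.pi * h * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0


def _perturbed_direction(rng, axis: np.ndarray, max_angle: float, planar: bool):
    axis = axis / np.linalg.norm(axis)
    if planar:
        angle = rng.uniform(-max_angle, max_angle)
        c, s = math.cos(angle), math.sin(angle)
        return np.array([axis[0] * c - axis[1] * s, axis[0] * s + axis[1] * c, 0.0])
    theta = rng.uniform(0.0, max_angle)
    phi = rng.uniform(0.0, 2 * math.pi)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return (
        math.cos(theta) * axis
        + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v)
    )


def gen_tree(spec: TreeSpec) -> Morphology:
    """Grow a connected tree with exactly ``spec.n_bifurcations`` bifurcations
    and ``spec.n_stems`` stems; every branch point is a bifurcation.

    The returned morphology carries a ``ground_truth``
    :class:`TreeGroundTruth` attribute with the totals accumulated while
    drawing (length, analytic frustum volume).
    """
    rng = np.random.default_rng(spec.seed)
    planar = spec.planarity == "planar"
    r_soma = 0.5 * spec.soma_diameter

    morph = Morphology(source_format="swc")
    soma = Section(id=1, kind=SOMA, points=[MorphPoint(0, 0, 0, spec.soma_diameter)],
                   name="soma[0]")
    morph.sections.append(soma)

    total_length = 0.0
    frustum_volume = 0.0
    next_id = 2
    seglen = lambda: rng.uniform(*spec.segment_length_range)

    def stem_direction(i: int):
        angle = 2 * math.pi * i / spec.n_stems + rng.uniform(-0.2, 0.2)
        if planar:
            return np.array([math.cos(angle), math.sin(angle), 0.0])
        zr = rng.uniform(-0.5, 0.5)
        d = np.array([math.cos(angle), math.sin(angle), zr])
        return d / np.linalg.norm(d)

    tips = []  # (section_id, last_index, position, direction, diameter)

    def grow_section(start, direction, diameter, parent_id, parent_idx, kind,
                     start_is_point, gap_r0):
        """Lay down one section starting at ``start``.

        When ``start_is_point`` the start coordinate becomes the section's
        first point (stems begin exactly on the soma surface); otherwise the
        first point sits one segment beyond the attachment point and the
        attachment edge tapers from ``gap_r0`` to the section's radius.
        """
        nonlocal next_id, total_length, frustum_volume
        pts = []
        pos = np.asarray(start, dtype=float)
        d = direction
        if start_is_point:
            pts.append(MorphPoint(*pos, diameter))
        prev_r = gap_r0
        n_steps = spec.points_per_section - (1 if start_is_point else 0)
        for _j in range(n_steps):
            step = seglen()
            d = _perturbed_direction(rng, d, 0.35, planar)
            pos = pos + step * d
            pts.append(MorphPoint(*pos, diameter))
            total_length += step
            frustum_volume += _frustum_vol(step, prev_r, 0.5 * diameter)
            prev_r = 0.5 * diameter
        sec = Section(id=next_id, kind=kind, points=pts, parent_id=parent_id,
                      parent_point_index=parent_idx,
                      name=f"{kind}[{next_id - 2}]")
        next_id += 1
        morph.sections.append(sec)
        tips.append((sec.id, len(pts) - 1, pos, d, diameter))
        return sec

    for i in range(spec.n_stems):
        direction = stem_direction(i)
        surface = r_soma * direction
        # soma-center-to-surface bridge frustum, at constant stem radius
        frustum_volume += _frustum_vol(
            r_soma, 0.5 * spec.stem_diameter, 0.5 * spec.stem_diameter
        )
        grow_section(surface, direction, spec.stem_diameter, soma.id, 0,
                     BASAL, start_is_point=True, gap_r0=0.5 * spec.stem_diameter)

    for _ in range(spec.n_bifurcations):
        k = int(rng.integers(0, len(tips)))
        sec_id, last_idx, pos, direction, diameter = tips.pop(k)
        child_d = diameter * spec.taper
        for _child in range(2):
            d = _perturbed_direction(rng, direction, 0.9, planar)
            # the attachment edge (parent tip -> child's first point) is the
            # child's first drawn step; its frustum tapers parent -> child
            grow_section(pos, d, child_d, sec_id, last_idx, BASAL,
                         start_is_point=False, gap_r0=0.5 * diameter)

    morph.ground_truth = TreeGroundTruth(
        total_length=total_length,
        frustum_volume=frustum_volume,
        n_bifurcations=spec.n_bifurcations,
        n_stems=spec.n_stems,
    )
    return morph


DEFECTS = ("detached_root", "zero_diameter", "amputated_planar")


def gen_defective(spec: TreeSpec, defect: str, slab: float = 20.0) -> Morphology:
    """Generate a tree and inject one named tracing defect.

    ``detached_root`` detaches the first stem (parent -1, shifted away from
    the soma); ``zero_diameter`` zeroes one point diameter; ``amputated_planar``
    truncates everything outside a z-slab of width ``slab`` centered on the
    soma, mimicking a cell cut out of a slice preparation.
    """
    if defect not in DEFECTS:
        raise NeuroprintError(f"unknown defect {defect!r}; choose from {DEFECTS}")
    m = gen_tree(spec)
    soma_ids = {s.id for s in m.soma_sections}

    if defect == "detached_root":
        stem = next(s for s in m.neurite_sections if s.parent_id in soma_ids)
        first = stem.points[0].xyz
        direction = first / np.linalg.norm(first)
        shift = 3.0 * direction
        subtree = {stem.id}
        changed = True
        while changed:
            changed = False
            for s in m.neurite_sections:
                if s.parent_id in subtree and s.id not in subtree:
                    subtree.add(s.id)
                    changed = True
        for sid in subtree:
            for p in m.section(sid).points:
                p.x += shift[0]
                p.y += shift[1]
                p.z += shift[2]
        stem.parent_id = None
        stem.parent_point_index = None
        m.detached_roots.append(stem.id)
        return m

    if defect == "zero_diameter":
        stem = next(iter(m.neurite_sections))
        stem.points[len(stem.points) // 2].diameter = 0.0
        return m

    # amputated_planar: truncate sections leaving the slab, then drop orphans
    z0 = m.soma_center()[2]
    removed = set()
    for sec in m.neurite_sections:
        cut = None
        for i, p in enumerate(sec.points):
            if abs(p.z - z0) > slab / 2:
                cut = i
                break
        if cut == 0:
            removed.add(sec.id)
        elif cut is not None:
            sec.points = sec.points[:cut]
    changed = True
    while changed:
        changed = False
        for sec in m.neurite_sections:
            if sec.id in removed:
                continue
            if sec.parent_id in removed:
                removed.add(sec.id)
                changed = True
            elif sec.parent_id not in soma_ids and sec.parent_id is not None:
                parent = m.section(sec.parent_id)
                if sec.parent_point_index >= len(parent.points):
                    removed.add(sec.id)
                    changed = True
    m.sections = [s for s in m.sections if s.id not in removed]
    return m


def gen_cluster(
    n_cells: int,
    convergence_point: Union[Sequence[float], None] = (0.0, 0.0, 80.0),
    seed: int = 0,
    ring_radius: float = 45.0,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    apical_diameter: float = 2.4,
    lateral_diameter: float = 2.0,
) -> List[Morphology]:
    """Generate ``n_cells`` distinct cells whose apical dendrites converge.

    Somata sit on a ring around ``center``; each cell's apical dendrite is a
    polyline ending 1 µm *past* ``convergence_point`` along its own approach
    direction, so every apical frustum strictly contains that point and the
    merged tessellation is one connected component by construction.  Lateral
    dendrites head tangentially around the ring, interleaving with the
    neighbors'.
    """
    if n_cells < 1:
        raise NeuroprintError("n_cells must be >= 1")
    center = np.asarray(center, dtype=float)
    conv = None if convergence_point is None else np.asarray(convergence_point, float)
    cells = []
    for i in range(n_cells):
        rng = np.random.default_rng(seed * 1000 + i)
        angle = 2 * math.pi * i / n_cells
        soma_pos = center + ring_radius * np.array(
            [math.cos(angle), math.sin(angle), 0.0]
        )
        m = Morphology(source_format="swc")
        soma = Section(id=1, kind=SOMA,
                       points=[MorphPoint(*soma_pos, 12.0)], name="soma[0]")
        m.sections.append(soma)
        next_id = 2

        if conv is not None:
            to_glom = conv - soma_pos
            dist = np.linalg.norm(to_glom)
            direction = to_glom / dist
            n_pts = 5
            pts = []
            for j in range(1, n_pts):
                frac = j / n_pts
                jitter = rng.normal(0.0, 1.0, 3) * (1 - frac)
                pts.append(MorphPoint(*(soma_pos + frac * to_glom + jitter),
                                      apical_diameter))
            overshoot = conv + 1.0 * direction
            pts.append(MorphPoint(*overshoot, apical_diameter))
            m.sections.append(
                Section(id=next_id, kind=APICAL, points=pts, parent_id=1,
                        parent_point_index=0, name="apical_dendrite[0]")
            )
            next_id += 1

        tangent = np.array([-math.sin(angle), math.cos(angle), 0.0])
        for sign in (+1.0, -1.0):
            d = sign * tangent + rng.normal(0.0, 0.15, 3)
            d /= np.linalg.norm(d)
            start = soma_pos + 6.0 * d
            pts = [MorphPoint(*start, lateral_diameter)]
            pos = start
            for _ in range(4):
                step = rng.uniform(8.0, 12.0)
                d2 = d + rng.normal(0.0, 0.2, 3)
                d = d2 / np.linalg.norm(d2)
                pos = pos + step * d
                pts.append(MorphPoint(*pos, lateral_diameter))
            m.sections.append(
                Section(id=next_id, kind=BASAL, points=pts,
                        parent_id=1, parent_point_index=0,
                        name=f"basal_dendrite[{next_id - 2}]")
            )
            next_id += 1
        cells.append(m)
    return cells
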