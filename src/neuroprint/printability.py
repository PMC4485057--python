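"""Printer-constraint validation of a configured model.

Commercial printing services impose a minimum thickness (typically 1 mm) on
wirey structures like dendrites and axons, and in practice models submitted
at ~1.2 mm print more reliably because the tessellated surface can run
slightly thinner than the logical skeleton.  Thickness is therefore checked
on the skeleton diameters, not the mesh: the check is resolution-independent
and conservative when the pipeline targets the recommended thickness.

The soma is exempt from the wirey-structure rules (its scaled extent still
counts toward the bounding box).  Structural risks that printers reject at
their own discretion — long unbranched neurite runs, a heavy soma on thin
stems — are reported as advisories only, never as pass/fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .edit import PrintSpec, soma_volume
from .errors import StatsError
from .meshio import MeshStats, PrintableVersion
from .morphology import Morphology

logger = logging.getLogger(__name__)


@dataclass
class ThicknessReport:
    """Outcome of the printed-thickness check.

    ``violations`` lists (section_id, point_index, printed_diameter_mm)
    below the hard minimum; ``advisories`` lists points between the minimum
    and the recommended thickness.  ``pass_flag`` is true iff there are no
    violations.
    """

    min_printed_by_section: dict  # section id -> min printed diameter (mm)
    violations: List[Tuple[int, int, float]]
    advisories: List[Tuple[int, int, float]]
    min_thickness: float
    recommended_thickness: float
    structural_advisories: List[str] = field(default_factory=list)

    @property
    def pass_flag(self) -> bool:
        return not self.violations

    @property
    def n_wirey_points(self) -> int:
        return sum(1 for _ in self.min_printed_by_section)


def check_thickness(m: Morphology, spec: PrintSpec) -> ThicknessReport:
    """Check every non-soma point's printed diameter against the spec.

    Printed diameter = diameter (input units) x coordinate_scale, read in
    output units.  A point below ``min_thickness`` is a violation; a point
    below ``recommended_thickness`` (but above the minimum) is an advisory.
    """
    if not m.sections:
        raise StatsError("empty morphology")
    min_by_sec = {}
    violations = []
    advisories = []
    for sec in m.neurite_sections:
        printed = np.array(
            [spec.printed_thickness(p.diameter) for p in sec.points]
        )
        min_by_sec[sec.id] = float(printed.min())
        # one-ulp slack: a diameter solved exactly for the threshold must pass
        tol = 1.0 - 1e-9
        for i, t in enumerate(printed):
            if t < spec.min_thickness * tol:
                violations.append((sec.id, i, float(t)))
            elif t < spec.recommended_thickness * tol:
                advisories.append((sec.id, i, float(t)))
    report = ThicknessReport(
        min_printed_by_section=min_by_sec,
        violations=violations,
        advisories=advisories,
        min_thickness=spec.min_thickness,
        recommended_thickness=spec.recommended_thickness,
        structural_advisories=_structural_advisories(m, spec),
    )
    if report.pass_flag:
        logger.info("thickness check passed (%d wirey sections)", len(min_by_sec))
    else:
        logger.warning(
            "thickness check failed: %d point(s) below %.3g mm",
            len(violations), spec.min_thickness,
        )
    return report


def suggest_diameter(spec: PrintSpec) -> float:
    """Fixed neurite diameter (input units) that prints at the recommended
    thickness: recommended_thickness / coordinate_scale."""
    return spec.recommended_thickness / spec.coordinate_scale


# Printed length above which an unbranched neurite run is flagged as a
# structural risk (mm); printers reject such models at their own discretion.
LONG_RUN_MM = 100.0
# Soma volume (mm^3) per mm of stem thickness above which a heavy-soma
# advisory is emitted.
SOMA_LOAD_RATIO = 2000.0


def _structural_advisories(
    m: Morphology, spec: PrintSpec, long_run_mm: float = LONG_RUN_MM,
    soma_load_ratio: float = SOMA_LOAD_RATIO,
) -> List[str]:
    out = []
    scale = spec.coordinate_scale
    for sec in m.neurite_sections:
        printed_len = sec.length() * scale
        if printed_len > long_run_mm:
            out.append(
                f"section {sec.id} ({sec.name}) is a {printed_len:.0f} mm "
                f"unbranched run; long thin runs may flex or break"
            )
    if m.soma_sections:
        soma_ids = {s.id for s in m.soma_sections}
        stems = [s for s in m.neurite_sections if s.parent_id in soma_ids]
        if stems:
            v = soma_volume(m) * scale**3
            thinnest = min(
                spec.printed_thickness(s.points[0].diameter) for s in stems
            )
            if thinnest > 0 and v / thinnest > soma_load_ratio:
                out.append(
                    f"heavy soma ({v:.0f} mm^3) supported by stems as thin "
                    f"as {thinnest:.2f} mm; may break in post-production"
                )
    return out


def printability_report(
    m: Morphology,
    spec: PrintSpec,
    stats: MeshStats,
    name: str = "model",
    comment: str = "",
    creator: str = "neuroprint",
    algorithm: str = "sdf-marching-cubes",
) -> Tuple[PrintableVersion, ThicknessReport]:
    """Assemble the printable-version metadata record plus thickness report."""
    if stats is None:
        raise StatsError("printability_report requires mesh statistics")
    record = PrintableVersion(
        name=name,
        comment=comment,
        magnification=spec.magnification,
        printed_volume=stats.volume,
        bbox=stats.bbox,
        algorithm=algorithm,
        creator=creator,
    )
    return record, check_thickness(m, spec)
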