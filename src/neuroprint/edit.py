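"""Diameter policies, soma rescaling, and scaling to print units.

Printers cannot reproduce micron-thin neurites at desk scale, so dendrite and
axon diameters are enlarged (lengths untouched) before meshing, the soma is
rescaled uniformly about its center of mass, and finally the whole model is
multiplied by a coordinate scale factor.  For morphologies measured in
microns and printer software expecting millimeters, a coordinate scale of 0.2
corresponds to a 200x magnification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

from .errors import NeuroprintError, PolicyError, RepairError
from .morphology import APICAL, BASAL, CUSTOM, SOMA, Morphology, Section

logger = logging.getLogger(__name__)

#: generic policy key covering basal, apical and custom neurites
DENDRITE = "dendrite"

_UNIT_TO_MM = {"um": 1e-3, "mm": 1.0}


@dataclass
class DiameterPolicy:
    """How to transform neurite point diameters (the soma is never touched).

    mode:
        ``fixed``   - set every diameter to ``value`` (µm)
        ``scale``   - multiply every diameter by ``value``
        ``floor``   - raise diameters below ``value`` (µm) up to it
        ``per_kind``- apply a (mode, value) pair per section kind from
                      ``per_kind_map``; keys are section kinds or the generic
                      ``"dendrite"`` covering basal/apical/custom
    """

    mode: str = "fixed"
    value: float = 1.0
    per_kind_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in {"fixed", "scale", "floor", "per_kind"}:
            raise PolicyError(f"unknown diameter policy mode {self.mode!r}")
        if self.mode != "per_kind" and self.value <= 0:
            raise PolicyError("diameter policy value must be positive")
        if SOMA in self.per_kind_map:
            raise PolicyError("per-kind diameter policies never target the soma")

    def _rule_for(self, kind: str) -> Optional[Tuple[str, float]]:
        if self.mode != "per_kind":
            return (self.mode, self.value)
        if kind in self.per_kind_map:
            return tuple(self.per_kind_map[kind])
        if kind in (BASAL, APICAL, CUSTOM) and DENDRITE in self.per_kind_map:
            return tuple(self.per_kind_map[DENDRITE])
        return None

    def transform(self, kind: str, diameter: float) -> float:
        rule = self._rule_for(kind)
        if rule is None:
            return diameter
        mode, value = rule
        if mode == "fixed":
            return float(value)
        if mode == "scale":
            return diameter * value
        if mode == "floor":
            return max(diameter, value)
        raise PolicyError(f"unknown diameter policy mode {mode!r}")


@dataclass
class PrintSpec:
    """Coordinate scaling and printer thickness constraints.

    ``coordinate_scale`` multiplies all coordinates/diameters; the printed
    size in ``output_unit`` of a feature of ``d`` input units is
    ``d * coordinate_scale`` (the scaled numbers are relabeled in the output
    unit).  Magnification is printed size over biological size:
    ``coordinate_scale * 1000`` for µm input and mm output.
    Thickness thresholds are in mm: commercial SLS services typically require
    a 1 mm minimum for wirey structures, and submitting 1.2 mm dendrites
    avoids borderline rejections.
    """

    coordinate_scale: float = 0.2
    input_unit: str = "um"
    output_unit: str = "mm"
    min_thickness: float = 1.0
    recommended_thickness: float = 1.2

    def __post_init__(self):
        if self.coordinate_scale <= 0:
            raise NeuroprintError("coordinate_scale must be positive")
        if self.min_thickness > self.recommended_thickness:
            raise NeuroprintError(
                "min_thickness must not exceed recommended_thickness"
            )
        if self.input_unit not in _UNIT_TO_MM or self.output_unit not in _UNIT_TO_MM:
            raise NeuroprintError(
                f"unsupported unit pair {self.input_unit!r} -> {self.output_unit!r}"
            )

    @property
    def unit_ratio(self) -> float:
        """Biological-size ratio between one input and one output unit."""
        return _UNIT_TO_MM[self.output_unit] / _UNIT_TO_MM[self.input_unit]

    @property
    def magnification(self) -> float:
        """Printed size over biological size (e.g. 0.2 µm→mm = 200x)."""
        return self.coordinate_scale * self.unit_ratio

    def printed_thickness(self, diameter: float) -> float:
        """Printed thickness (output units) of a feature ``diameter`` input
        units across."""
        return diameter * self.coordinate_scale


# ---------------------------------------------------------------------------
# Soma geometry helpers (frustum chains and spheres)
# ---------------------------------------------------------------------------

def frustum_volume(h: float, r0: float, r1: float) -> float:
    """Volume of a truncated cone of height h and end radii r0, r1."""
    return math.pi * h * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0


def frustum_centroid_offset(h: float, r0: float, r1: float) -> float:
    """Axial distance from the r0 end to the frustum's centroid."""
    denom = r0 * r0 + r0 * r1 + r1 * r1
    if denom == 0:
        return 0.5 * h
    return h * (r0 * r0 + 2 * r0 * r1 + 3 * r1 * r1) / (4.0 * denom)


def _soma_primitives(m: Morphology):
    """Yield (volume, centroid) for each solid primitive of the soma."""
    for sec in m.soma_sections:
        pts = sec.xyz()
        radii = 0.5 * sec.diameters()
        if len(sec.points) == 1:
            r = radii[0]
            yield (4.0 / 3.0) * math.pi * r**3, pts[0]
        else:
            for i in range(len(pts) - 1):
                a, b = pts[i], pts[i + 1]
                h = float(np.linalg.norm(b - a))
                if h == 0:
                    continue
                v = frustum_volume(h, radii[i], radii[i + 1])
                t = frustum_centroid_offset(h, radii[i], radii[i + 1]) / h
                yield v, a + t * (b - a)


def soma_center_of_mass(m: Morphology) -> np.ndarray:
    """Volume-weighted centroid of the soma solid."""
    if m.soma_sections:
        total_v = 0.0
        acc = np.zeros(3)
        for v, c in _soma_primitives(m):
            total_v += v
            acc += v * np.asarray(c)
        if total_v > 0:
            return acc / total_v
        # zero-volume chain: fall back to the mean of the points
        return np.concatenate([s.xyz() for s in m.soma_sections]).mean(axis=0)
    if m.soma_outline is not None:
        return np.asarray(m.soma_outline, dtype=float).mean(axis=0)
    raise RepairError("morphology has no soma")


def soma_volume(m: Morphology) -> float:
    """Analytic volume of the soma solid (sphere or frustum chain)."""
    return sum(v for v, _ in _soma_primitives(m))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_diameter_policy(m: Morphology, policy: DiameterPolicy) -> Morphology:
    """Transform non-soma point diameters; coordinates are never changed."""
    out = m.copy()
    for sec in out.sections:
        if sec.is_soma:
            continue
        for pt in sec.points:
            new_d = policy.transform(sec.kind, pt.diameter)
            if new_d <= 0:
                raise PolicyError(
                    f"policy produced non-positive diameter {new_d} on "
                    f"section {sec.id} (kind {sec.kind})"
                )
            pt.diameter = new_d
    return out


def scale_soma(m: Morphology, factor: float) -> Morphology:
    """Uniformly scale soma positions and diameters about its center of mass.

    Equivalent to scaling about the origin and translating the soma back so
    its volume-weighted center of mass is unchanged.  Neurite sections keep
    their measured coordinates; the watertight tessellation absorbs any
    surface gap or overlap at the attachment points.
    """
    if factor <= 0:
        raise NeuroprintError("soma scale factor must be positive")
    if not m.has_soma:
        raise RepairError("cannot scale soma: morphology has no soma")
    out = m.copy()
    if factor == 1.0:
        return out
    com_before = soma_center_of_mass(out)
    for sec in out.soma_sections:
        for pt in sec.points:
            pt.x *= factor
            pt.y *= factor
            pt.z *= factor
            pt.diameter *= factor
    if out.soma_outline is not None:
        out.soma_outline = np.asarray(out.soma_outline, dtype=float) * factor
    com_after = soma_center_of_mass(out)
    shift = com_before - com_after
    for sec in out.soma_sections:
        for pt in sec.points:
            pt.x += shift[0]
            pt.y += shift[1]
            pt.z += shift[2]
    if out.soma_outline is not None:
        out.soma_outline = out.soma_outline + shift
    return out


def scale_model(obj, spec: PrintSpec):
    """Multiply all coordinates (and diameters) by ``spec.coordinate_scale``.

    Works on a :class:`Morphology` or on a triangle mesh (anything with a
    ``vertices`` array).  Returns ``(scaled object, magnification)``.
    """
    s = spec.coordinate_scale
    if isinstance(obj, Morphology):
        out = obj.copy()
        for sec in out.sections:
            for pt in sec.points:
                pt.x *= s
                pt.y *= s
                pt.z *= s
                pt.diameter *= s
        if out.soma_outline is not None:
            out.soma_outline = np.asarray(out.soma_outline, dtype=float) * s
        return out, spec.magnification
    if hasattr(obj, "vertices"):
        import copy as _copy

        out = _copy.deepcopy(obj)
        out.vertices = np.asarray(out.vertices, dtype=float) * s
        return out, spec.magnification
    raise NeuroprintError(f"cannot scale object of type {type(obj).__name__}")
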