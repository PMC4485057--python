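"""End-to-end pipeline: tracing file(s) in, printable mesh + metadata out.

Stage order: read -> repair (reattach detached roots, optionally drop the
axon) -> diameter policy -> soma scale -> thickness check -> tessellate ->
optional coloring -> scale to print units -> stats -> metadata -> export.
Every stage is logged with its parameters and timing; a run manifest
(config hash, package version, stage timings) is written next to the
outputs so any run can be re-executed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

from . import __version__
from .colors import ColorScheme, assign_colors, map_triangles_to_segments
from .edit import (DiameterPolicy, PrintSpec, apply_diameter_policy,
                   scale_model, scale_soma)
from .errors import NeuroprintError
from .meshio import mesh_stats, write_stl, write_wrl
from .morphology import Morphology, read_asc, read_swc, repair_detached, remove_axon
from .printability import ThicknessReport, check_thickness, printability_report
from .surface import MeshResolution, merge_cells, skeleton_to_frusta

logger = logging.getLogger(__name__)


class ThicknessViolation(NeuroprintError):
    """Raised when the model violates the printer's minimum thickness."""

    def __init__(self, report: ThicknessReport):
        self.report = report
        super().__init__(
            f"{len(report.violations)} point(s) print thinner than the "
            f"{report.min_thickness} mm minimum (pass force=True to override)"
        )


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    inputs: List[str]
    input_format: str = "auto"  # auto | swc | asc
    reattach: bool = True
    drop_axon: bool = False
    diameter_policy: Optional[DiameterPolicy] = None
    soma_scale: float = 1.0
    print_spec: PrintSpec = field(default_factory=PrintSpec)
    resolution: MeshResolution = field(default_factory=MeshResolution)
    color: Optional[ColorScheme] = None
    stl_path: Optional[str] = None
    wrl_path: Optional[str] = None
    metadata_path: Optional[str] = None
    name: str = "model"
    force: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        def plain(v):
            if v is None or isinstance(v, (int, float, str, bool)):
                return v
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if hasattr(v, "__dict__"):
                return {k: plain(w) for k, w in vars(v).items()}
            return str(v)

        return {k: plain(v) for k, v in vars(self).items()}

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if isinstance(payload.get("diameter_policy"), dict):
            payload["diameter_policy"] = DiameterPolicy(**payload["diameter_policy"])
        if isinstance(payload.get("print_spec"), dict):
            payload["print_spec"] = PrintSpec(**payload["print_spec"])
        if isinstance(payload.get("resolution"), dict):
            payload["resolution"] = MeshResolution(**payload["resolution"])
        if isinstance(payload.get("color"), dict):
            payload["color"] = ColorScheme(**payload["color"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _read_cell(path: str, fmt: str) -> Morphology:
    if fmt == "auto":
        fmt = "asc" if str(path).lower().endswith(".asc") else "swc"
    if fmt == "swc":
        return read_swc(path)
    if fmt == "asc":
        return read_asc(path)
    raise NeuroprintError(f"unknown input format {fmt!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns meshes, metadata and reports.

    Thickness violations abort with :class:`ThicknessViolation` unless
    ``config.force`` is set.  Identical config and inputs produce identical
    outputs.
    """
    timings = {}
    result = {}

    def stage(label):
        class _Timer:
            def __enter__(self):
                logger.info("stage %s ...", label)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[label] = round(time.perf_counter() - self.t0, 4)
                if exc_type is not None:
                    logger.error("stage %s failed: %s", label, exc)

        return _Timer()

    with stage("read"):
        cells = [_read_cell(p, config.input_format) for p in config.inputs]
        if not cells:
            raise NeuroprintError("no input files")

    with stage("repair"):
        if config.drop_axon:
            cells = [remove_axon(c) for c in cells]
        if config.reattach:
            cells = [repair_detached(c) if c.detached_roots else c for c in cells]

    with stage("diameter_policy"):
        if config.diameter_policy is not None:
            cells = [apply_diameter_policy(c, config.diameter_policy) for c in cells]

    with stage("soma_scale"):
        if config.soma_scale != 1.0:
            cells = [scale_soma(c, config.soma_scale) for c in cells]

    with stage("thickness_check"):
        reports = [check_thickness(c, config.print_spec) for c in cells]
        result["thickness_reports"] = reports
        bad = [r for r in reports if not r.pass_flag]
        if bad and not config.force:
            raise ThicknessViolation(bad[0])

    with stage("tessellate"):
        mesh = merge_cells(cells, config.resolution)

    with stage("color"):
        if config.color is not None:
            frusta = []
            for c in cells:
                frusta.extend(skeleton_to_frusta(c))
            assignment = map_triangles_to_segments(mesh, frusta)
            # section ids are per-cell; coloring uses the first cell's section
            # table, which is exact for single-cell runs
            mesh = assign_colors(mesh, assignment, config.color, cells[0])

    with stage("scale"):
        mesh, magnification = scale_model(mesh, config.print_spec)
        result["magnification"] = magnification

    with stage("stats"):
        stats = mesh_stats(mesh, unit=config.print_spec.output_unit)
        result["mesh_stats"] = stats

    with stage("metadata"):
        record, _ = printability_report(
            cells[0], config.print_spec, stats, name=config.name
        )
        result["printable_version"] = record

    with stage("export"):
        outputs = {}
        if config.stl_path:
            write_stl(mesh, config.stl_path, binary=True)
            outputs["stl"] = config.stl_path
        if config.wrl_path:
            write_wrl(mesh, config.wrl_path)
            outputs["wrl"] = config.wrl_path
        if config.metadata_path:
            Path(config.metadata_path).write_text(record.to_json() + "\n")
            outputs["metadata"] = config.metadata_path
        result["outputs"] = outputs

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "neuroprint_version": __version__,
        "stage_timings_s": timings,
    }
    result["manifest"] = manifest
    result["mesh"] = mesh
    if config.metadata_path:
        manifest_path = Path(config.metadata_path).with_suffix(".manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return result
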