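"""File formats, run configuration and report generation.

All deliverable formats are plain text: two-column ASCII depth-dose
curves, ASCII dose-plane grids with ``#`` headers, CSV spot lists and
spot logs, JSON/YAML beam libraries and reports.  Every format has a
reader and a writer whose composition is the identity on valid files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .beam_model import (
    BeamLibrary,
    BortfeldParams,
    DepthDoseCurve,
    InputError,
    LateralKernelParams,
    MachineConfig,
)
from .dose_engine import DosePlane, Field, Spot

__all__ = [
    "FORMAT_VERSION",
    "read_depth_dose", "write_depth_dose",
    "read_dose_plane", "write_dose_plane",
    "read_field_csv", "write_field_csv",
    "read_field_json", "write_field_json",
    "read_beam_library", "write_beam_library",
    "RunConfig", "load_run_config",
    "PsqaReport", "write_report", "read_report_json",
    "file_sha256",
]

FORMAT_VERSION = "1"


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# depth-dose curves: two-column ASCII, '#' comments
# --------------------------------------------------------------------------

def write_depth_dose(curve: DepthDoseCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("# spotqa depth-dose v%s\n" % FORMAT_VERSION)
        if np.isfinite(curve.energy_label):
            fh.write(f"# energy_mev={float(curve.energy_label)!r}\n")
        fh.write("# depth_gcm2  value_per_mu\n")
        for d, v in zip(curve.depths, curve.values):
            fh.write(f"{float(d)!r} {float(v)!r}\n")


def read_depth_dose(path) -> DepthDoseCurve:
    energy = float("nan")
    depths, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "energy_mev=" in line:
                    energy = float(line.split("energy_mev=")[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise InputError(f"bad depth-dose line: {line!r}")
            depths.append(float(parts[0]))
            values.append(float(parts[1]))
    return DepthDoseCurve(np.array(depths), np.array(values), energy)


# --------------------------------------------------------------------------
# dose planes: ASCII grid with header comments
# --------------------------------------------------------------------------

def write_dose_plane(plane: DosePlane, path) -> None:
    with open(path, "w") as fh:
        fh.write("# spotqa dose-plane v%s\n" % FORMAT_VERSION)
        fh.write(f"# depth_gcm2={float(plane.depth)!r}\n")
        fh.write(f"# origin_mm={float(plane.origin_x)!r} {float(plane.origin_y)!r}\n")
        fh.write(f"# spacing_mm={float(plane.spacing)!r}\n")
        for row in plane.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_dose_plane(path) -> DosePlane:
    depth = None
    origin = None
    spacing = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "depth_gcm2=" in line:
                    depth = float(line.split("depth_gcm2=")[1])
                elif "origin_mm=" in line:
                    ox, oy = line.split("origin_mm=")[1].split()
                    origin = (float(ox), float(oy))
                elif "spacing_mm=" in line:
                    spacing = float(line.split("spacing_mm=")[1])
                continue
            rows.append([float(v) for v in line.split()])
    if depth is None or origin is None or spacing is None:
        raise InputError(f"{path}: missing dose-plane header fields")
    vals = np.array(rows, dtype=float)
    if vals.ndim != 2 or any(len(r) != len(rows[0]) for r in rows):
        raise InputError(f"{path}: non-rectangular grid")
    return DosePlane(vals, origin[0], origin[1], spacing, depth)


# --------------------------------------------------------------------------
# fields: CSV + JSON sidecar, or single-file JSON
# --------------------------------------------------------------------------

_FIELD_HEADER = "layer,energy_mev,x_mm,y_mm,mu"


def write_field_csv(fld: Field, path, library: BeamLibrary | None = None) -> None:
    """CSV spot list plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    energies = library.machine.energies_mev if library is not None else None
    with open(path, "w") as fh:
        fh.write(_FIELD_HEADER + "\n")
        for s in fld.spots:
            e = energies[s.energy_index] if energies is not None else float("nan")
            fh.write(f"{s.energy_index},{float(e)!r},{float(s.x)!r},{float(s.y)!r},{float(s.mu)!r}\n")
    sidecar = {
        "format_version": FORMAT_VERSION,
        "field_id": fld.field_id,
        "gantry_angle": fld.gantry_angle,
        "range_shifter": fld.range_shifter,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_field_csv(path) -> Field:
    path = Path(path)
    spots = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _FIELD_HEADER:
            raise InputError(f"{path}: bad field header {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise InputError(f"{path}:{ln}: expected 5 fields")
            spots.append(Spot(int(parts[0]), float(parts[2]), float(parts[3]), float(parts[4])))
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return Field(
        spots=spots,
        field_id=meta.get("field_id", path.stem),
        gantry_angle=float(meta.get("gantry_angle", 0.0)),
        range_shifter=bool(meta.get("range_shifter", False)),
    )


def write_field_json(fld: Field, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "field_id": fld.field_id,
        "gantry_angle": fld.gantry_angle,
        "range_shifter": fld.range_shifter,
        "spots": [
            {"energy_index": s.energy_index, "x_mm": s.x, "y_mm": s.y, "mu": s.mu}
            for s in fld.spots
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_field_json(path) -> Field:
    with open(path) as fh:
        doc = json.load(fh)
    spots = [
        Spot(int(s["energy_index"]), float(s["x_mm"]), float(s["y_mm"]), float(s["mu"]))
        for s in doc["spots"]
    ]
    return Field(
        spots=spots,
        field_id=doc.get("field_id", "field"),
        gantry_angle=float(doc.get("gantry_angle", 0.0)),
        range_shifter=bool(doc.get("range_shifter", False)),
    )


# --------------------------------------------------------------------------
# beam library: versioned YAML/JSON document
# --------------------------------------------------------------------------

def _library_doc(lib: BeamLibrary) -> dict:
    return {
        "schema_version": lib.schema_version,
        "machine": {
            "energies_mev": list(lib.machine.energies_mev),
            "ranges_gcm2": list(lib.machine.ranges_gcm2),
            "max_field_mm": lib.machine.max_field_mm,
            "rs_wet_gcm2": lib.machine.rs_wet_gcm2,
            "rs_physical_cm": lib.machine.rs_physical_cm,
            "default_spacing_mm": lib.machine.default_spacing_mm,
        },
        "bragg": [
            {k: float(v) for k, v in dataclasses.asdict(b).items()} for b in lib.bragg
        ],
        "kernels": [
            {
                "sigma1_coef": [float(c) for c in k.sigma1_coef],
                "sigma2_coef": [float(c) for c in k.sigma2_coef],
                "s_coef": [float(c) for c in k.s_coef],
                "w2_coef": [float(c) for c in k.w2_coef],
                "wcl_coef": [float(c) for c in k.wcl_coef],
                "sigma_air1": float(k.sigma_air1),
                "sigma_air2": float(k.sigma_air2),
                "w_air": float(k.w_air),
            }
            for k in lib.kernels
        ],
    }


def write_beam_library(lib: BeamLibrary, path) -> None:
    """Serialize as YAML or JSON depending on the file extension."""
    doc = _library_doc(lib)
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(doc, fh, sort_keys=True)
        else:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_beam_library(path) -> BeamLibrary:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    m = doc["machine"]
    machine = MachineConfig(
        energies_mev=tuple(m["energies_mev"]),
        ranges_gcm2=tuple(m["ranges_gcm2"]),
        max_field_mm=float(m["max_field_mm"]),
        rs_wet_gcm2=float(m["rs_wet_gcm2"]),
        rs_physical_cm=float(m["rs_physical_cm"]),
        default_spacing_mm=float(m.get("default_spacing_mm", 1.0)),
    )
    bragg = tuple(BortfeldParams(**b).validate() for b in doc["bragg"])
    kernels = tuple(
        LateralKernelParams(
            sigma1_coef=tuple(k["sigma1_coef"]),
            sigma2_coef=tuple(k["sigma2_coef"]),
            s_coef=tuple(k["s_coef"]),
            w2_coef=tuple(k["w2_coef"]),
            wcl_coef=tuple(k["wcl_coef"]),
            sigma_air1=float(k["sigma_air1"]),
            sigma_air2=float(k["sigma_air2"]),
            w_air=float(k["w_air"]),
        ).validate()
        for k in doc["kernels"]
    )
    return BeamLibrary(machine=machine, bragg=bragg, kernels=kernels,
                       schema_version=str(doc.get("schema_version", "1")))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Clinic-style run configuration; CLI flags override these values."""

    beam_library: str | None = None
    criteria: tuple = ((2.0, 2.0), (3.0, 3.0))   # (dose_pct, dta_mm) gates
    threshold_pct: float = 10.0
    search_mm: float = 3.0
    step_mm: float = 1.0
    action_level_pct: float = 90.0
    output_dir: str = "."
    seed: int = 0
    schema_version: str = FORMAT_VERSION

    def __post_init__(self):
        if not 0.0 < self.action_level_pct <= 100.0:
            raise InputError("action level must be in (0, 100]")
        for pct, dta in self.criteria:
            if pct <= 0 or dta <= 0:
                raise InputError("criteria must be positive")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    crit = doc.get("criteria")
    if crit is not None:
        doc["criteria"] = tuple((float(c[0]), float(c[1])) for c in crit)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


# --------------------------------------------------------------------------
# PSQA report
# --------------------------------------------------------------------------

@dataclass
class PsqaReport:
    """Draft per-field PSQA report: everything traceable to an artifact."""

    field_id: str
    criteria_results: list = field(default_factory=list)
    # each: {"label", "dose_pct", "dta_mm", "pass_rate", "n_evaluated", "max_gamma"}
    point_dose_diff_pct: float | None = None
    table_2p5d: list = field(default_factory=list)
    # each: {"offset_mm", "depth_gcm2", "pass_rate"}
    disposition: dict = field(default_factory=dict)
    log_summary: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PsqaReport":
        return cls(**d)


def _fmt(x, nd=1):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "-"
    return f"{x:.{nd}f}"


def render_report_markdown(report: PsqaReport) -> str:
    """Human-readable draft PSQA report (fixed precision for stable bytes)."""
    lines = [f"# PSQA report — field `{report.field_id}`", ""]
    if report.point_dose_diff_pct is not None:
        lines += [f"Point-dose difference: {_fmt(report.point_dose_diff_pct)}%", ""]
    if report.criteria_results:
        lines += ["## Gamma analysis", "",
                  "| criteria | pass rate (%) | evaluated | max gamma |",
                  "|---|---|---|---|"]
        for c in report.criteria_results:
            lines.append(
                f"| {c['label']} | {_fmt(c['pass_rate'])} | {c['n_evaluated']} "
                f"| {_fmt(c.get('max_gamma'), 2)} |"
            )
        lines.append("")
    if report.table_2p5d:
        lines += ["## 2.5D depth search", "",
                  "| depth offset (mm) | depth (g/cm2) | pass rate (%) |",
                  "|---|---|---|"]
        for row in report.table_2p5d:
            lines.append(
                f"| {_fmt(row['offset_mm'])} | {_fmt(row['depth_gcm2'], 2)} "
                f"| {_fmt(row['pass_rate'])} |"
            )
        lines.append("")
    if report.disposition:
        d = report.disposition
        lines += ["## Disposition", "",
                  f"**{d.get('status', '?').upper()}** via {d.get('route', '?')}"]
        ev = d.get("evidence", {})
        if ev:
            shown = ", ".join(f"{k}={_fmt(v) if isinstance(v, float) else v}"
                              for k, v in sorted(ev.items()))
            lines.append(f"Evidence: {shown}")
        lines.append("")
    if report.log_summary:
        lines += ["## Delivery-log summary", ""]
        for k, v in sorted(report.log_summary.items()):
            lines.append(f"- {k}: {_fmt(v, 3) if isinstance(v, float) else v}")
        lines.append("")
    if report.provenance:
        lines += ["## Provenance", ""]
        for k, v in sorted(report.provenance.items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
    return "\n".join(lines)


def write_report(report: PsqaReport, path, fmt: str = "json") -> None:
    """Write the report as schema-valid JSON or rendered markdown."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "markdown":
        with open(path, "w") as fh:
            fh.write(render_report_markdown(report))
    else:
        raise InputError(f"unknown report format {fmt!r}")


def read_report_json(path) -> PsqaReport:
    with open(path) as fh:
        return PsqaReport.from_dict(json.load(fh))
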