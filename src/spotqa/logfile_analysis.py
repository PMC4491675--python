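"""Spot-delivery log analytics.

Parses per-spot, per-fraction delivery records (planned vs recorded
position and MU), computes deviation statistics in the style of the
clinical log-file panels (deviation maps, histograms vs X and vs Y,
cross-fraction reproducibility), reconstructs "as delivered" fields for
dose recomputation, and runs pattern-based periodic QA checks against
squares/diagonals with known perturbations.

Log schema (CSV, one row per spot per fraction)::

    fraction,layer,spot,planned_x_mm,planned_y_mm,recorded_x_mm,recorded_y_mm,planned_mu,recorded_mu
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .beam_model import InputError, ValidationError
from .dose_engine import DosePlane, Field, GridSpec, PhantomGeometry, Spot, compute_dose_plane

__all__ = [
    "SpotLogRecord",
    "DeviationReport",
    "PatternSpec",
    "SpotLogParseError",
    "LOG_COLUMNS",
    "parse_spot_log",
    "write_spot_log",
    "records_to_frame",
    "deviation_stats",
    "reconstruct_field_from_log",
    "planned_vs_delivered_dose",
    "pattern_qa_check",
]

LOG_COLUMNS = (
    "fraction",
    "layer",
    "spot",
    "planned_x_mm",
    "planned_y_mm",
    "recorded_x_mm",
    "recorded_y_mm",
    "planned_mu",
    "recorded_mu",
)


class SpotLogParseError(ValueError):
    """Parse failure; carries the offending line numbers and messages."""

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"spot log parse failed: {lines}{more}")


@dataclass(frozen=True)
class SpotLogRecord:
    fraction: int
    layer: int
    spot: int
    planned_x: float
    planned_y: float
    recorded_x: float
    recorded_y: float
    planned_mu: float
    recorded_mu: float

    def validate(self) -> "SpotLogRecord":
        if self.fraction < 0 or self.layer < 0 or self.spot < 0:
            raise ValidationError("indices must be >= 0")
        if self.planned_mu < 0 or self.recorded_mu < 0:
            raise ValidationError("MU values must be >= 0")
        return self


@dataclass(frozen=True)
class PatternSpec:
    """Periodic-QA spot pattern: a square lattice or a diagonal line.

    ``perturbations`` lists (spot index, dx mm, dy mm) applied at delivery
    time to selected spots; the conventional magnitudes are 1, 2 and 3 mm.
    """

    kind: str                  # "square" | "diagonal"
    pitch_mm: float
    extent_mm: float
    perturbations: tuple = ()

    def __post_init__(self):
        if self.kind not in ("square", "diagonal"):
            raise ValidationError("kind must be 'square' or 'diagonal'")
        if self.pitch_mm <= 0 or self.extent_mm <= 0:
            raise ValidationError("pitch and extent must be positive")
        object.__setattr__(
            self,
            "perturbations",
            tuple((int(i), float(dx), float(dy)) for i, dx, dy in self.perturbations),
        )

    def n_spots(self) -> int:
        n1 = int(round(self.extent_mm / self.pitch_mm)) + 1
        return n1 * n1 if self.kind == "square" else n1

    def positions(self) -> np.ndarray:
        """(n, 2) planned spot positions, centered on the origin."""
        n1 = int(round(self.extent_mm / self.pitch_mm)) + 1
        c = np.arange(n1) * self.pitch_mm - self.extent_mm / 2.0
        if self.kind == "square":
            xx, yy = np.meshgrid(c, c)
            return np.column_stack([xx.ravel(), yy.ravel()])
        return np.column_stack([c, c])


# --------------------------------------------------------------------------
# parsing / serialization
# --------------------------------------------------------------------------

def parse_spot_log(source) -> list:
    """Parse the spot-log CSV.  ``source`` is a path or an open text file.

    Every malformed row is collected and reported with its line number in
    a single :class:`SpotLogParseError`.
    """
    if hasattr(source, "read"):
        return _parse_stream(source)
    with open(source, "r", newline="") as fh:
        return _parse_stream(fh)


def _parse_stream(fh) -> list:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise SpotLogParseError([(1, "empty file, header expected")])
    header = [h.strip() for h in header]
    if tuple(header) != LOG_COLUMNS:
        raise SpotLogParseError(
            [(1, f"bad header {header!r}, expected {list(LOG_COLUMNS)}")]
        )
    records, errors = [], []
    for ln, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(LOG_COLUMNS):
            errors.append((ln, f"expected {len(LOG_COLUMNS)} fields, got {len(row)}"))
            continue
        try:
            rec = SpotLogRecord(
                fraction=int(row[0]),
                layer=int(row[1]),
                spot=int(row[2]),
                planned_x=float(row[3]),
                planned_y=float(row[4]),
                recorded_x=float(row[5]),
                recorded_y=float(row[6]),
                planned_mu=float(row[7]),
                recorded_mu=float(row[8]),
            ).validate()
        except (ValueError, ValidationError) as exc:
            errors.append((ln, str(exc)))
            continue
        records.append(rec)
    if errors:
        raise SpotLogParseError(errors)
    return records


def write_spot_log(records: Sequence[SpotLogRecord], dest) -> None:
    """Write records in the log CSV schema (path or open text file)."""

    def _write(fh):
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(LOG_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.fraction, r.layer, r.spot,
                    repr(r.planned_x), repr(r.planned_y),
                    repr(r.recorded_x), repr(r.recorded_y),
                    repr(r.planned_mu), repr(r.recorded_mu),
                ]
            )

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w", newline="") as fh:
            _write(fh)


def records_to_frame(records: Sequence[SpotLogRecord]) -> pd.DataFrame:
    if not records:
        raise InputError("no records")
    df = pd.DataFrame([r.__dict__ for r in records])
    # spots delivered in multiple bursts within a fraction are aggregated
    # MU-weighted before any analysis
    key = ["fraction", "layer", "spot"]
    if df.duplicated(key).any():
        def agg(g):
            w = g["recorded_mu"].to_numpy()
            wsum = w.sum()
            if wsum <= 0:
                w = np.ones(len(g))
                wsum = len(g)
            return pd.Series({
                "planned_x": g["planned_x"].iloc[0],
                "planned_y": g["planned_y"].iloc[0],
                "recorded_x": float((g["recorded_x"] * w).sum() / wsum),
                "recorded_y": float((g["recorded_y"] * w).sum() / wsum),
                "planned_mu": g["planned_mu"].iloc[0],
                "recorded_mu": float(wsum),
            })
        df = df.groupby(key, as_index=False).apply(agg, include_groups=False)
    df["dx"] = df["recorded_x"] - df["planned_x"]
    df["dy"] = df["recorded_y"] - df["planned_y"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["dmu_pct"] = np.where(
            df["planned_mu"] > 0,
            100.0 * (df["recorded_mu"] - df["planned_mu"]) / df["planned_mu"],
            0.0,
        )
    return df


# --------------------------------------------------------------------------
# deviation statistics
# --------------------------------------------------------------------------

def _axis_stats(v: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        "max_abs": float(np.max(np.abs(v))),
    }


@dataclass
class DeviationReport:
    """Aggregate and stratified spot-position / MU deviation statistics."""

    n_records: int
    dx: dict
    dy: dict
    dmu_pct: dict
    per_layer: pd.DataFrame
    per_fraction: pd.DataFrame
    reproducibility_sd_mm: float          # pooled per-spot cross-fraction SD
    per_spot_sd: pd.DataFrame             # per-spot SDs (>= 2 fractions only)
    hist_dx: tuple                        # (counts, bin_edges)
    hist_dy: tuple
    dev_vs_x: pd.DataFrame                # binned |dev| profile vs planned x
    dev_vs_y: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "dx": self.dx,
            "dy": self.dy,
            "dmu_pct": self.dmu_pct,
            "reproducibility_sd_mm": self.reproducibility_sd_mm,
            "per_layer": self.per_layer.to_dict(orient="list"),
            "per_fraction": self.per_fraction.to_dict(orient="list"),
            "hist_dx": {
                "counts": [int(c) for c in self.hist_dx[0]],
                "edges": [float(e) for e in self.hist_dx[1]],
            },
            "hist_dy": {
                "counts": [int(c) for c in self.hist_dy[0]],
                "edges": [float(e) for e in self.hist_dy[1]],
            },
        }


def deviation_stats(
    records: Sequence[SpotLogRecord],
    *,
    hist_bin_mm: float = 0.1,
    hist_range_mm: float = 2.0,
    profile_bin_mm: float = 20.0,
) -> DeviationReport:
    """Deviation analytics: recorded minus planned, per axis and per MU.

    Histograms use 0.1 mm bins over +/-2 mm by default (resolving the
    0.2 mm reproducibility scale); overflow deviations are clipped into
    the edge bins so counts always sum to the record count.
    Cross-fraction reproducibility is the pooled SD of recorded positions
    per spot, over spots observed in at least two fractions.
    """
    if not records:
        raise InputError("deviation_stats requires at least one record")
    df = records_to_frame(records)

    edges = np.arange(-hist_range_mm, hist_range_mm + hist_bin_mm / 2, hist_bin_mm)
    hx = np.histogram(np.clip(df["dx"], edges[0], edges[-1] - 1e-12), bins=edges)
    hy = np.histogram(np.clip(df["dy"], edges[0], edges[-1] - 1e-12), bins=edges)

    def strat(key):
        rows = []
        for k, g in df.groupby(key):
            rows.append({
                key: k,
                "n": len(g),
                "dx_mean": g["dx"].mean(), "dx_sd": g["dx"].std(ddof=1) if len(g) > 1 else 0.0,
                "dy_mean": g["dy"].mean(), "dy_sd": g["dy"].std(ddof=1) if len(g) > 1 else 0.0,
                "dx_max_abs": g["dx"].abs().max(), "dy_max_abs": g["dy"].abs().max(),
                "dmu_pct_mean": g["dmu_pct"].mean(),
            })
        return pd.DataFrame(rows)

    # cross-fraction reproducibility: pooled SD of recorded position per spot
    gs = df.groupby(["layer", "spot"])
    per_spot = gs.agg(
        n_fractions=("fraction", "nunique"),
        sd_x=("recorded_x", lambda v: v.std(ddof=1)),
        sd_y=("recorded_y", lambda v: v.std(ddof=1)),
    ).reset_index()
    multi = per_spot[per_spot["n_fractions"] >= 2]
    if len(multi):
        dof = (multi["n_fractions"] - 1).to_numpy()
        pooled_var = float(
            np.sum(dof * (multi["sd_x"] ** 2) + dof * (multi["sd_y"] ** 2))
            / (2 * np.sum(dof))
        )
        repro = float(np.sqrt(pooled_var))
    else:
        repro = float("nan")

    def profile(coord, dev):
        lo = np.floor(df[coord].min() / profile_bin_mm) * profile_bin_mm
        hi = np.ceil(df[coord].max() / profile_bin_mm) * profile_bin_mm + profile_bin_mm / 2
        bins = np.arange(lo, hi + profile_bin_mm, profile_bin_mm)
        cut = pd.cut(df[coord], bins=bins, include_lowest=True)
        g = df.groupby(cut, observed=True)[dev]
        return pd.DataFrame({
            "bin_center": [iv.mid for iv in g.mean().index],
            "mean": g.mean().to_numpy(),
            "sd": g.std(ddof=1).fillna(0.0).to_numpy(),
            "n": g.size().to_numpy(),
        })

    return DeviationReport(
        n_records=len(df),
        dx=_axis_stats(df["dx"].to_numpy()),
        dy=_axis_stats(df["dy"].to_numpy()),
        dmu_pct=_axis_stats(df["dmu_pct"].to_numpy()),
        per_layer=strat("layer"),
        per_fraction=strat("fraction"),
        reproducibility_sd_mm=repro,
        per_spot_sd=per_spot,
        hist_dx=hx,
        hist_dy=hy,
        dev_vs_x=profile("planned_x", "dx"),
        dev_vs_y=profile("planned_y", "dy"),
    )


# --------------------------------------------------------------------------
# delivered-dose reconstruction
# --------------------------------------------------------------------------

def reconstruct_field_from_log(
    records: Sequence[SpotLogRecord],
    fraction,
    *,
    template: Field | None = None,
    field_id: str = "delivered",
) -> Field:
    """Field carrying the *recorded* positions and MUs of one fraction.

    ``fraction="mean"`` uses fraction-averaged recorded positions and the
    mean recorded MU per spot.  Layer indices map to energy indices via
    the planned ``template`` when given (by layer order), else the layer
    index is used as the energy index directly.
    """
    df = records_to_frame(records)
    if fraction == "mean":
        sel = df.groupby(["layer", "spot"], as_index=False).agg(
            recorded_x=("recorded_x", "mean"),
            recorded_y=("recorded_y", "mean"),
            recorded_mu=("recorded_mu", "mean"),
        )
    else:
        sel = df[df["fraction"] == int(fraction)]
        if sel.empty:
            raise InputError(f"fraction {fraction} not present in the log")

    layer_to_energy = None
    if template is not None:
        layers_sorted = sorted({s.energy_index for s in template.spots}, reverse=True)
        log_layers = sorted(sel["layer"].unique())
        if len(log_layers) > len(layers_sorted):
            raise InputError("log has more layers than the planned template")
        # log layer 0 = first delivered = deepest layer
        layer_to_energy = {
            int(ll): int(layers_sorted[i]) for i, ll in enumerate(log_layers)
        }

    spots = []
    for _, row in sel.sort_values(["layer", "spot"]).iterrows():
        ei = int(row["layer"]) if layer_to_energy is None else layer_to_energy[int(row["layer"])]
        spots.append(Spot(ei, float(row["recorded_x"]), float(row["recorded_y"]), float(row["recorded_mu"])))
    rs = template.range_shifter if template is not None else False
    return Field(spots=spots, field_id=field_id, range_shifter=rs)


@dataclass
class DeliveredDoseComparison:
    max_diff_pct: float      # max |delivered - planned| as % of planned max
    mean_diff_pct: float
    gamma: "object"          # GammaResult
    planned: DosePlane
    delivered: DosePlane


def planned_vs_delivered_dose(
    fld: Field,
    records: Sequence[SpotLogRecord],
    fraction,
    library,
    phantom: PhantomGeometry,
    depth: float,
    grid: GridSpec,
    criteria=None,
) -> DeliveredDoseComparison:
    """Compute planned and log-reconstructed planes with the same engine."""
    from .gamma_analysis import GammaCriteria, gamma_2d

    planned = compute_dose_plane(library, fld, phantom, depth, grid)
    delivered_field = reconstruct_field_from_log(records, fraction, template=fld)
    delivered = compute_dose_plane(library, delivered_field, phantom, depth, grid)

    norm = float(planned.values.max())
    if norm <= 0:
        raise InputError("planned plane carries no dose")
    diff = np.abs(delivered.values - planned.values) / norm * 100.0
    crit = criteria if criteria is not None else GammaCriteria()
    gres = gamma_2d(planned, delivered, crit)
    return DeliveredDoseComparison(
        max_diff_pct=float(diff.max()),
        mean_diff_pct=float(diff.mean()),
        gamma=gres,
        planned=planned,
        delivered=delivered,
    )


# --------------------------------------------------------------------------
# pattern QA
# --------------------------------------------------------------------------

def pattern_qa_check(
    records: Sequence[SpotLogRecord],
    spec: PatternSpec,
    tolerance_mm: float = 0.5,
) -> pd.DataFrame:
    """Flag pattern spots whose mean recorded deviation exceeds tolerance.

    Returns one row per pattern spot: estimated (dx, dy) = mean recorded -
    planned across fractions, the deviation magnitude, and the flag.
    """
    if tolerance_mm <= 0:
        raise InputError("tolerance must be positive")
    pos = spec.positions()
    df = records_to_frame(records)
    if df["layer"].nunique() != 1:
        raise InputError("a pattern log must contain a single layer")
    n_log = df["spot"].nunique()
    if n_log != len(pos):
        raise InputError(
            f"pattern/record mismatch: pattern has {len(pos)} spots, log has {n_log}"
        )
    est = df.groupby("spot", as_index=False).agg(
        planned_x=("planned_x", "first"),
        planned_y=("planned_y", "first"),
        dx=("dx", "mean"),
        dy=("dy", "mean"),
        n_fractions=("fraction", "nunique"),
    )
    if not np.allclose(est[["planned_x", "planned_y"]].to_numpy(), pos, atol=1e-6):
        raise InputError("log planned positions do not match the pattern lattice")
    est["magnitude_mm"] = np.hypot(est["dx"], est["dy"])
    est["flagged"] = est["magnitude_mm"] > tolerance_mm
    return est
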