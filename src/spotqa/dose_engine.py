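"""Pencil-beam dose superposition in a water phantom.

Dose at a plane of water-equivalent depth z is the superposition over
spots of ``mu_i * IDD(E_i, z_eff) * K(r_i; z_eff, E_i)`` with
``z_eff = z + rs_wet`` when a range shifter is in the beam.  Parallel-beam
approximation: spot lateral positions are depth-independent.

Coordinate convention (used everywhere): right-handed, x/y in mm at the
isocenter plane; plane "depth" is water-equivalent distance from the
phantom surface in g/cm^2; grids are corner-origin, row-major with y
increasing along rows-axis 0 and x along axis 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .beam_model import (
    BeamLibrary,
    DepthDoseCurve,
    InputError,
    ValidationError,
    bortfeld_idd,
    kernel_mass_within,
    kernel_truncation_radius,
    lateral_kernel,
)

__all__ = [
    "Spot",
    "Field",
    "PhantomGeometry",
    "GridSpec",
    "DosePlane",
    "effective_depth",
    "compute_dose_plane",
    "compute_dose_at_points",
    "compute_depth_dose",
]


@dataclass(frozen=True)
class Spot:
    """One scanned pencil beam: energy layer, lateral position, weight."""

    energy_index: int
    x: float    # mm at isocenter
    y: float    # mm
    mu: float   # monitor units, >= 0

    def validate(self, max_field_mm: float | None = None) -> "Spot":
        if self.energy_index < 0:
            raise ValidationError("energy_index must be >= 0")
        if self.mu < 0:
            raise ValidationError("mu must be >= 0")
        if max_field_mm is not None:
            half = max_field_mm / 2.0
            if abs(self.x) > half or abs(self.y) > half:
                raise ValidationError(
                    f"spot ({self.x}, {self.y}) outside field limit +/-{half} mm"
                )
        return self


@dataclass
class Field:
    """An ordered list of spots grouped by energy layer — the unit of QA."""

    spots: list
    field_id: str = "field"
    gantry_angle: float = 0.0
    range_shifter: bool = False

    def validate(self, machine=None) -> "Field":
        if len(self.spots) == 0:
            raise ValidationError("a field must contain at least one spot")
        limit = machine.max_field_mm if machine is not None else None
        for s in self.spots:
            s.validate(limit)
        return self

    def layers(self) -> dict:
        """Spots grouped by energy index, deepest (highest index) first."""
        out: dict = {}
        for s in self.spots:
            out.setdefault(s.energy_index, []).append(s)
        return dict(sorted(out.items(), key=lambda kv: -kv[0]))


@dataclass(frozen=True)
class PhantomGeometry:
    """Water phantom with an optional upstream water-equivalent shift."""

    rs_wet_gcm2: float = 0.0   # 0 means no range shifter in the beam

    def __post_init__(self):
        if self.rs_wet_gcm2 < 0:
            raise ValidationError("rs_wet_gcm2 must be >= 0")


@dataclass(frozen=True)
class GridSpec:
    """Corner-origin lateral grid: origin (mm), pitch (mm), shape (ny, nx)."""

    origin_x: float
    origin_y: float
    spacing: float
    nx: int
    ny: int

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise ValidationError("grid shape must be at least 1x1")

    def x_coords(self) -> np.ndarray:
        return self.origin_x + self.spacing * np.arange(self.nx)

    def y_coords(self) -> np.ndarray:
        return self.origin_y + self.spacing * np.arange(self.ny)


@dataclass
class DosePlane:
    """2D dose grid at a stated water-equivalent depth."""

    values: np.ndarray          # (ny, nx), row-major, y along axis 0
    origin_x: float             # mm, corner
    origin_y: float             # mm
    spacing: float              # mm
    depth: float                # g/cm^2
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("values must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        return self.origin_x + self.spacing * np.arange(self.values.shape[1])

    def y_coords(self) -> np.ndarray:
        return self.origin_y + self.spacing * np.arange(self.values.shape[0])

    def grid(self) -> GridSpec:
        ny, nx = self.values.shape
        return GridSpec(self.origin_x, self.origin_y, self.spacing, nx, ny)


def effective_depth(depth: float, phantom: PhantomGeometry) -> float:
    """Depth used for IDD/kernel lookup: physical depth + rs_wet."""
    if depth < 0:
        raise InputError("depth must be non-negative")
    return depth + phantom.rs_wet_gcm2


def _spot_kernel_on_grid(dxv, dyv, z_eff, kparams):
    """Truncated, renormalized kernel evaluated on an offset grid."""
    rmax = kernel_truncation_radius(z_eff, kparams)
    r = np.hypot(dxv[None, :], dyv[:, None])
    k = np.zeros_like(r)
    mask = r <= rmax
    if np.any(mask):
        k[mask] = lateral_kernel(r[mask], z_eff, kparams)
        k /= kernel_mass_within(rmax, z_eff, kparams)
    return k


def compute_dose_plane(
    library: BeamLibrary,
    fld: Field,
    phantom: PhantomGeometry,
    depth: float,
    grid: GridSpec,
) -> DosePlane:
    """Superpose all spots of a field onto one lateral plane.

    Kernels are truncated at ``8*sigma2 + 5*s`` and the truncated mass is
    renormalized, so each spot's plane integral remains ``mu * IDD``.
    """
    fld.validate(library.machine)
    if depth < 0:
        raise InputError("depth must be non-negative")
    z_eff = effective_depth(depth, phantom)
    meta = {"depth_eff_gcm2": z_eff, "field_id": fld.field_id}
    if z_eff > library.max_range + 2.0:
        meta["warning"] = "plane beyond the deepest configured range"

    vals = np.zeros((grid.ny, grid.nx), dtype=float)
    kx = np.arange(grid.nx)
    ky = np.arange(grid.ny)
    for ei, spots in fld.layers().items():
        idd = float(library.idd(ei, z_eff))
        if idd == 0.0:
            continue
        kparams = library.kernel_params(ei)
        for s in spots:
            if s.mu == 0.0:
                continue
            # relative coordinates formed as (origin - spot) + k*spacing so a
            # joint shift of grid and spots is bit-identical
            dxv = (grid.origin_x - s.x) + grid.spacing * kx
            dyv = (grid.origin_y - s.y) + grid.spacing * ky
            # mu applied last so dose is exactly (bit-wise) linear in MU
            vals += s.mu * (idd * _spot_kernel_on_grid(dxv, dyv, z_eff, kparams))
    return DosePlane(vals, grid.origin_x, grid.origin_y, grid.spacing, depth, meta)


def compute_dose_at_points(
    library: BeamLibrary,
    fld: Field,
    phantom: PhantomGeometry,
    depth: float,
    x,
    y,
) -> np.ndarray:
    """Point-wise dose at depth ``depth`` for arbitrary lateral positions."""
    fld.validate(library.machine)
    if depth < 0:
        raise InputError("depth must be non-negative")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    z_eff = effective_depth(depth, phantom)
    out = np.zeros(np.broadcast(x, y).shape, dtype=float)
    for ei, spots in fld.layers().items():
        idd = float(library.idd(ei, z_eff))
        if idd == 0.0:
            continue
        kparams = library.kernel_params(ei)
        rmax = kernel_truncation_radius(z_eff, kparams)
        mass = kernel_mass_within(rmax, z_eff, kparams)
        for s in spots:
            if s.mu == 0.0:
                continue
            r = np.hypot(x - s.x, y - s.y)
            m = r <= rmax
            if np.any(m):
                out[m] += s.mu * (idd / mass * lateral_kernel(r[m], z_eff, kparams))
    return out


def compute_depth_dose(
    library: BeamLibrary,
    fld: Field,
    phantom: PhantomGeometry,
    x: float,
    y: float,
    depths: Sequence[float],
) -> DepthDoseCurve:
    """Central- or off-axis depth dose at a lateral point ``(x, y)``."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise InputError("depth list must not be empty")
    if np.any(np.diff(depths) <= 0):
        raise InputError("depths must be strictly ascending")
    vals = np.array(
        [float(compute_dose_at_points(library, fld, phantom, d, x, y)[0]) for d in depths]
    )
    vals = np.clip(vals, 0.0, None)
    return DepthDoseCurve(depths=depths, values=vals, energy_label=float("nan"))
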