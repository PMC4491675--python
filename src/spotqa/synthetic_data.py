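"""Synthetic inputs with controlled ground truth.

Every input the toolkit consumes can be generated here: beam libraries,
uniform-dose and modulated fields, periodic-QA spot patterns, simulated
"measured" planes (noise / lateral shift / depth offset), and simulated
delivery logs.  All generators are pure functions of their parameters and
seed, and each emits its ground truth alongside the artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from scipy.optimize import nnls

from .beam_model import (
    BeamLibrary,
    BortfeldParams,
    InputError,
    LateralKernelParams,
    MachineConfig,
    bortfeld_idd,
    calibrate_range_energy,
    energy_from_range,
)
from .dose_engine import (
    DosePlane,
    Field,
    GridSpec,
    PhantomGeometry,
    Spot,
    compute_depth_dose,
    compute_dose_plane,
)
from .logfile_analysis import PatternSpec, SpotLogRecord

__all__ = [
    "NoiseModel",
    "JitterModel",
    "DEFAULT_CALIBRATION_POINTS",
    "make_beam_library",
    "make_uniform_field",
    "modulate_field",
    "make_pattern_field",
    "simulate_measurement",
    "simulate_log",
]

# machine-table endpoints used for the two-point range-energy calibration:
# 72.5 MeV -> 4.0 g/cm^2 and 221.8 MeV -> 30.6 g/cm^2
DEFAULT_CALIBRATION_POINTS = ((72.5, 4.0), (221.8, 30.6))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise stand-in for a 2D detector plane."""

    multiplicative_sd: float = 0.0   # fractional
    additive_sd: float = 0.0         # dose units
    lateral_shift: tuple = (0.0, 0.0)   # (dx, dy) mm
    depth_offset_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise InputError("noise SDs must be >= 0")


@dataclass(frozen=True)
class JitterModel:
    """Spot-delivery jitter: systematic offset + per-axis random scatter."""

    systematic: tuple = (0.0, 0.0)   # (dx, dy) mm
    random_sd: float = 0.0           # mm per axis
    mu_sd: float = 0.0               # fractional MU noise
    n_fractions: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.random_sd < 0 or self.mu_sd < 0:
            raise InputError("jitter SDs must be >= 0")
        if self.n_fractions < 1:
            raise InputError("n_fractions must be >= 1")


# --------------------------------------------------------------------------
# beam library
# --------------------------------------------------------------------------

def make_beam_library(
    n_energies: int = 94,
    range_span: tuple = (4.0, 30.6),
    *,
    calibration_points=DEFAULT_CALIBRATION_POINTS,
    epsilon: float = 0.1,
    sigma_frac: float = 0.012,
    sigma_floor: float = 0.08,
) -> BeamLibrary:
    """Physically plausible beam library over an even range grid.

    Ranges are evenly spaced across ``range_span``; energies follow the
    two-point power-law calibration.  Straggling widths grow with range
    (``sigma = sigma_floor + sigma_frac * R0``), lateral widths grow with
    depth, and every kernel integrates to 1 by construction.
    """
    if n_energies < 2:
        raise InputError("need at least 2 energies")
    lo, hi = float(range_span[0]), float(range_span[1])
    if not (0.0 < lo < hi <= 40.0):
        raise InputError("range span must be ascending within (0, 40] g/cm^2")

    alpha, p = calibrate_range_energy(calibration_points)
    ranges = np.linspace(lo, hi, n_energies)
    energies = energy_from_range(ranges, alpha, p)

    bragg = []
    kernels = []
    for e, r0 in zip(np.atleast_1d(energies), ranges):
        sigma = sigma_floor + sigma_frac * r0
        bragg.append(
            BortfeldParams(
                r0=float(r0), sigma=float(sigma), epsilon=epsilon, phi=1.0,
                p=p, alpha=alpha, energy_mev=float(e),
            ).validate()
        )
        # in-air spot size shrinks with energy: ~6 mm at the lowest energy
        # down to ~3 mm at the highest; scattering growth with depth
        frac = (r0 - lo) / (hi - lo)
        sa1 = 6.0 - 3.0 * frac
        sa2 = 2.0 * sa1
        kernels.append(
            LateralKernelParams(
                sigma1_coef=(sa1, 0.12, 0.004),
                sigma2_coef=(sa2, 0.18, 0.004),
                s_coef=(5.0, 0.3),
                w2_coef=(0.1,),
                wcl_coef=(0.05,),
                sigma_air1=sa1,
                sigma_air2=sa2,
                w_air=0.1,
            ).validate(zmax=hi + 5.0)
        )

    machine = MachineConfig(
        energies_mev=tuple(np.atleast_1d(energies)),
        ranges_gcm2=tuple(ranges),
        rs_wet_gcm2=max(lo - 0.3, 0.0),   # shallowest range maps to 0.3 g/cm^2
    )
    return BeamLibrary(machine=machine, bragg=tuple(bragg), kernels=tuple(kernels))


# --------------------------------------------------------------------------
# fields
# --------------------------------------------------------------------------

@dataclass
class UniformFieldResult:
    field: Field
    layer_indices: list
    layer_weights: np.ndarray
    flatness_pct: float          # max central-axis deviation over the span
    span: tuple                  # (proximal, distal) g/cm^2


def make_uniform_field(
    library: BeamLibrary,
    target_range: float,
    modulation: float,
    field_size_mm: float = 60.0,
    spot_pitch_mm: float = 5.0,
    *,
    mu_scale: float = 1.0,
    evaluate_flatness: bool = True,
) -> UniformFieldResult:
    """Single-field-uniform-dose style field with solved layer weights.

    Layers whose nominal ranges fall in ``[target_range - modulation,
    target_range]`` are selected, spot positions form a square lattice,
    and per-layer weights are solved by nonnegative least squares so the
    central-axis depth dose is flat over the modulated span.  Flatness is
    reported as the max % deviation of the engine-computed central-axis
    dose from its span mean.
    """
    if modulation < 0 or modulation > target_range:
        raise InputError("modulation must be in [0, target_range]")
    if spot_pitch_mm <= 0:
        raise InputError("spot pitch must be positive")
    ranges = np.asarray(library.machine.ranges_gcm2)
    span = (target_range - modulation, target_range)
    sel = np.nonzero((ranges >= span[0] - 1e-9) & (ranges <= span[1] + 1e-9))[0]
    if len(sel) == 0:
        raise InputError("no energy layers inside the requested span")
    if modulation == 0:
        sel = sel[-1:]

    # solve nonnegative layer weights against the central-axis IDD matrix;
    # the flat region conventionally ends ~2 straggling widths proximal of
    # the deepest Bragg peak (the distal falloff is not flattenable)
    sigma_deep = library.bragg[sel[-1]].sigma
    flat_hi = max(span[1] - 2.0 * sigma_deep, span[0])
    if len(sel) == 1:
        weights = np.array([1.0])
    else:
        zq = np.linspace(span[0], flat_hi, 4 * len(sel))
        A = np.column_stack([bortfeld_idd(zq, library.bragg[i]) for i in sel])
        weights, _ = nnls(A, np.ones(len(zq)))
        if weights.max() <= 0:
            raise InputError("weight solve degenerated to zero")
        weights = weights / weights.max()

    n1 = int(round(field_size_mm / spot_pitch_mm)) + 1
    c = np.arange(n1) * spot_pitch_mm - field_size_mm / 2.0
    spots = []
    for i, w in zip(sel, weights):
        if w <= 0:
            continue
        mu = float(mu_scale * w)
        for y in c:
            for x in c:
                spots.append(Spot(int(i), float(x), float(y), mu))
    fld = Field(spots=spots, field_id=f"sfud_r{target_range:g}_m{modulation:g}")

    flat = 0.0
    if evaluate_flatness and modulation > 0 and flat_hi > span[0]:
        phantom = PhantomGeometry()
        depths = np.linspace(span[0], flat_hi, 25)
        curve = compute_depth_dose(library, fld, phantom, 0.0, 0.0, depths)
        mean = float(curve.values.mean())
        flat = 100.0 * float(np.max(np.abs(curve.values - mean)) / mean)
    return UniformFieldResult(
        field=fld,
        layer_indices=[int(i) for i in sel],
        layer_weights=weights,
        flatness_pct=flat,
        span=(span[0], flat_hi),
    )


def modulate_field(fld: Field, *, correlation_mm: float = 20.0, sd_log: float = 0.4,
                   seed: int = 0) -> Field:
    """IMPT-like heterogeneity: multiply spot MUs by a smooth log-normal field."""
    rng = np.random.default_rng(seed)
    xs = np.array([s.x for s in fld.spots])
    ys = np.array([s.y for s in fld.spots])
    n = 48
    gx = np.linspace(xs.min() - 1, xs.max() + 1, n)
    gy = np.linspace(ys.min() - 1, ys.max() + 1, n)
    px = (gx[-1] - gx[0]) / (n - 1)
    white = rng.standard_normal((n, n))
    smooth = gaussian_filter(white, max(correlation_mm / max(px, 1e-9), 1e-6))
    smooth = smooth / max(smooth.std(), 1e-12) * sd_log
    f = RegularGridInterpolator((gy, gx), np.exp(smooth), bounds_error=False, fill_value=1.0)
    factors = f(np.column_stack([ys, xs]))
    spots = [
        Spot(s.energy_index, s.x, s.y, float(s.mu * fac))
        for s, fac in zip(fld.spots, factors)
    ]
    return Field(spots=spots, field_id=fld.field_id + "_mod",
                 gantry_angle=fld.gantry_angle, range_shifter=fld.range_shifter)


def make_pattern_field(
    spec: PatternSpec,
    *,
    energy_index: int = 0,
    mu: float = 1.0,
) -> tuple:
    """Spots on the pattern lattice plus the ground-truth perturbation table.

    The field carries the *planned* (unperturbed) lattice; the returned
    table lists ``(spot_index, dx, dy, magnitude)`` for the spots that are
    perturbed at delivery time, so logs simulated from it carry known
    offsets.
    """
    pos = spec.positions()
    for i, dx, dy in spec.perturbations:
        if not 0 <= i < len(pos):
            raise InputError(f"perturbation index {i} out of range")
    spots = [Spot(energy_index, float(x), float(y), mu) for x, y in pos]
    fld = Field(spots=spots, field_id=f"pattern_{spec.kind}")
    truth = [
        {"spot": i, "dx_mm": dx, "dy_mm": dy, "magnitude_mm": float(math.hypot(dx, dy))}
        for i, dx, dy in spec.perturbations
    ]
    return fld, truth


# --------------------------------------------------------------------------
# simulated measurement and delivery log
# --------------------------------------------------------------------------

def simulate_measurement(
    plane: DosePlane,
    noise: NoiseModel,
    *,
    recompute=None,
) -> DosePlane:
    """Turn a calculated plane into a synthetic "measured" plane.

    Order of effects: depth offset (plane recomputed at the shifted depth
    when a ``recompute(depth_gcm2) -> DosePlane`` closure is given), then
    lateral shift (bilinear resampling, zero fill outside), then
    multiplicative and additive Gaussian noise under the model seed.
    Provenance is recorded in ``meta``.
    """
    values = plane.values
    depth = plane.depth
    if noise.depth_offset_mm != 0.0:
        if recompute is None:
            raise InputError("depth_offset requires an engine recompute closure")
        shifted = recompute(plane.depth + noise.depth_offset_mm / 10.0)
        values = shifted.values
    dx, dy = noise.lateral_shift
    if dx != 0.0 or dy != 0.0:
        ny, nx = values.shape
        if abs(dx) >= nx * plane.spacing or abs(dy) >= ny * plane.spacing:
            raise InputError("lateral shift exceeds the grid extent")
        interp = RegularGridInterpolator(
            (plane.y_coords(), plane.x_coords()), values,
            bounds_error=False, fill_value=0.0,
        )
        X, Y = np.meshgrid(plane.x_coords(), plane.y_coords())
        # measurement shifted by (dx, dy): sample the source at r - shift
        values = interp(np.stack([Y - dy, X - dx], axis=-1))
    rng = np.random.default_rng(noise.seed)
    out = values.copy()
    if noise.multiplicative_sd > 0:
        out = out * (1.0 + rng.normal(0.0, noise.multiplicative_sd, out.shape))
    if noise.additive_sd > 0:
        out = out + rng.normal(0.0, noise.additive_sd, out.shape)
    out = np.clip(out, 0.0, None)
    meta = dict(plane.meta)
    meta["synthetic_measurement"] = {
        "multiplicative_sd": noise.multiplicative_sd,
        "additive_sd": noise.additive_sd,
        "lateral_shift_mm": list(noise.lateral_shift),
        "depth_offset_mm": noise.depth_offset_mm,
        "seed": noise.seed,
    }
    return DosePlane(out, plane.origin_x, plane.origin_y, plane.spacing, depth, meta)


def simulate_log(
    fld: Field,
    jitter: JitterModel,
    *,
    spot_offsets=None,
) -> list:
    """Per-fraction delivery records for a field under a jitter model.

    recorded = planned + systematic (+ per-spot offset from
    ``spot_offsets``: mapping spot index -> (dx, dy)) + N(0, random_sd)
    per axis; recorded MU = planned MU * (1 + N(0, mu_sd)).  Layer index 0
    is the deepest (first delivered) layer.
    """
    rng = np.random.default_rng(jitter.seed)
    offsets = dict(spot_offsets) if spot_offsets else {}
    layer_of = {}
    for li, (ei, _) in enumerate(fld.layers().items()):
        layer_of[ei] = li
    spot_counter: dict = {}
    layout = []   # (layer, spot_in_layer, global_index, Spot)
    for gi, s in enumerate(fld.spots):
        li = layer_of[s.energy_index]
        k = spot_counter.get(li, 0)
        spot_counter[li] = k + 1
        layout.append((li, k, gi, s))

    records = []
    sx, sy = jitter.systematic
    for fr in range(jitter.n_fractions):
        for li, k, gi, s in layout:
            odx, ody = offsets.get(gi, (0.0, 0.0))
            ex = rng.normal(0.0, jitter.random_sd) if jitter.random_sd > 0 else 0.0
            ey = rng.normal(0.0, jitter.random_sd) if jitter.random_sd > 0 else 0.0
            emu = rng.normal(0.0, jitter.mu_sd) if jitter.mu_sd > 0 else 0.0
            records.append(
                SpotLogRecord(
                    fraction=fr, layer=li, spot=k,
                    planned_x=s.x, planned_y=s.y,
                    recorded_x=s.x + sx + odx + ex,
                    recorded_y=s.y + sy + ody + ey,
                    planned_mu=s.mu,
                    recorded_mu=max(s.mu * (1.0 + emu), 0.0),
                )
            )
    return records
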