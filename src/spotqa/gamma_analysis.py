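"""Dose-distribution comparison: point dose, 2D / 2.5D / 3D gamma, QA cascade.

The gamma index of a reference point r with dose D_r against an evaluated
distribution D_e is

    gamma(r) = min over e of sqrt( |r - e|^2 / dta^2
                                   + (D_e(e) - D_r)^2 / (pct * norm / 100)^2 )

with a *global* dose criterion (norm = reference maximum unless given)
and a low-dose threshold applied to the reference plane only: reference
points below threshold are excluded from both numerator and denominator
of the pass rate.  A point passes when gamma <= 1 (boundary inclusive).

Two routes are provided: a fast search (coarse offset lattice at dta/10
plus local refinement) and an exhaustive brute-force lattice search that
serves as an independent oracle for small grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .beam_model import InputError, ValidationError
from .dose_engine import DosePlane

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "QaDisposition",
    "point_dose_difference",
    "gamma_2d",
    "gamma_2d_bruteforce",
    "gamma_2p5d",
    "Gamma25dResult",
    "gamma_3d",
    "qa_disposition",
]

MM_PER_GCM2 = 10.0  # water: 1 g/cm^2 of depth = 10 mm


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria: %dose (global) / DTA mm, with a low-dose cutoff."""

    dose_pct: float = 3.0
    dta_mm: float = 3.0
    threshold_pct: float = 10.0
    normalization: float | None = None  # None -> reference-plane maximum

    def __post_init__(self):
        if self.dose_pct <= 0 or self.dta_mm <= 0 or self.threshold_pct <= 0:
            raise ValidationError("criteria must be positive")
        if self.threshold_pct >= 100:
            raise ValidationError("threshold_pct must be < 100")
        if self.normalization is not None and self.normalization <= 0:
            raise ValidationError("normalization must be positive")

    def label(self) -> str:
        return f"{self.dose_pct:g}%/{self.dta_mm:g}mm"


@dataclass
class GammaResult:
    """Per-point gamma map (NaN = below threshold / outside overlap)."""

    gamma_map: np.ndarray
    pass_rate: float            # % of evaluated points with gamma <= 1
    n_evaluated: int
    criteria: GammaCriteria
    meta: dict = field(default_factory=dict)

    @property
    def max_gamma(self) -> float:
        if self.n_evaluated == 0:
            return float("nan")
        return float(np.nanmax(self.gamma_map))


@dataclass
class QaDisposition:
    """Outcome of the pass / review / fail cascade with its evidence."""

    status: str                  # "pass" | "review" | "fail"
    route: str                   # which gate decided
    evidence: dict = field(default_factory=dict)


def point_dose_difference(measured: float, calculated: float, normalization: float) -> float:
    """Signed % difference of a point dose pair, relative to ``normalization``."""
    if normalization <= 0:
        raise InputError("normalization must be positive")
    return 100.0 * (measured - calculated) / normalization


# --------------------------------------------------------------------------
# 2D gamma
# --------------------------------------------------------------------------

def _disk_offsets(step: float, radius: float):
    n = int(math.floor(radius / step))
    d = step * np.arange(-n, n + 1)
    dx, dy = np.meshgrid(d, d)
    keep = np.hypot(dx, dy) <= radius + 1e-12
    return dx[keep], dy[keep]


def _plane_interpolator(plane: DosePlane) -> Callable:
    interp = RegularGridInterpolator(
        (plane.y_coords(), plane.x_coords()),
        plane.values,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )

    def f(xq, yq):
        return interp(np.stack([yq, xq], axis=-1))

    return f


def _reference_points(reference: DosePlane, evaluated: DosePlane, criteria: GammaCriteria):
    norm = criteria.normalization if criteria.normalization is not None else float(
        np.max(reference.values)
    )
    if norm <= 0:
        raise InputError("reference plane has no positive dose to normalize to")
    thresh = criteria.threshold_pct / 100.0 * norm

    xr, yr = reference.x_coords(), reference.y_coords()
    ex0, ex1 = evaluated.x_coords()[0], evaluated.x_coords()[-1]
    ey0, ey1 = evaluated.y_coords()[0], evaluated.y_coords()[-1]
    if xr[-1] < ex0 or xr[0] > ex1 or yr[-1] < ey0 or yr[0] > ey1:
        raise InputError("reference and evaluated planes do not overlap")

    X, Y = np.meshgrid(xr, yr)
    inside = (X >= ex0) & (X <= ex1) & (Y >= ey0) & (Y <= ey1)
    mask = (reference.values >= thresh) & inside
    return norm, mask, X[mask], Y[mask], reference.values[mask]


def _finish(reference, criteria, mask, gam, meta) -> GammaResult:
    gmap = np.full(reference.values.shape, np.nan)
    gmap[mask] = gam
    n_eval = int(mask.sum())
    if n_eval == 0:
        meta = dict(meta, warning="no points above the low-dose threshold")
        rate = float("nan")
    else:
        rate = 100.0 * float(np.count_nonzero(gam <= 1.0 + 1e-12)) / n_eval
    return GammaResult(gmap, rate, n_eval, criteria, meta)


def _gamma_gradient_scale(evaluated: DosePlane, dose_crit: float) -> float:
    """Max gradient of the evaluated surface in gamma units (1/mm)."""
    v = evaluated.values
    g = 0.0
    if v.shape[1] > 1:
        g = max(g, float(np.max(np.abs(np.diff(v, axis=1)))))
    if v.shape[0] > 1:
        g = max(g, float(np.max(np.abs(np.diff(v, axis=0)))))
    return max(g / (evaluated.spacing * dose_crit), 1e-6)


def gamma_2d(
    reference: DosePlane,
    evaluated: DosePlane,
    criteria: GammaCriteria,
    *,
    search_factor: float = 3.0,
    coarse_step: float | None = None,
    refine_candidates: int = 6,
    refine_levels: int = 3,
) -> GammaResult:
    """Fast 2D gamma: adaptive coarse disk search + multi-candidate refinement.

    The evaluated plane is interpolated bilinearly.  The coarse lattice
    step adapts to the steepest dose gradient (in gamma units) so that
    narrow dose-crossing basins stay visible; the ``refine_candidates``
    best coarse offsets per point are then polished with shrinking local
    searches.  The search disk radius is ``search_factor * dta`` (gamma
    values beyond it are disk minima, i.e. lower bounds >= search_factor —
    irrelevant for the pass rate).
    """
    norm, mask, X, Y, Dref = _reference_points(reference, evaluated, criteria)
    dose_crit = criteria.dose_pct / 100.0 * norm
    dta = criteria.dta_mm
    interp = _plane_interpolator(evaluated)

    gscale = _gamma_gradient_scale(evaluated, dose_crit)
    if coarse_step is not None:
        step = coarse_step
    else:
        step = float(np.clip(0.5 / gscale, dta / 100.0, dta / 10.0))
    offx, offy = _disk_offsets(step, search_factor * dta)

    npts = X.size
    K = max(1, int(refine_candidates))
    topg = np.full((K, npts), np.inf)
    topdx = np.zeros((K, npts))
    topdy = np.zeros((K, npts))

    chunk = max(1, int(4_000_000 // max(1, npts)))
    for i0 in range(0, len(offx), chunk):
        dx = offx[i0 : i0 + chunk][:, None]
        dy = offy[i0 : i0 + chunk][:, None]
        de = interp((X[None, :] + dx).ravel(), (Y[None, :] + dy).ravel()).reshape(dx.shape[0], npts)
        g2 = (dx * dx + dy * dy) / (dta * dta) + ((de - Dref[None, :]) / dose_crit) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        allg = np.concatenate([topg, g2], axis=0)
        alldx = np.concatenate([topdx, np.broadcast_to(dx, g2.shape)], axis=0)
        alldy = np.concatenate([topdy, np.broadcast_to(dy, g2.shape)], axis=0)
        sel = np.argpartition(allg, K - 1, axis=0)[:K]
        topg = np.take_along_axis(allg, sel, axis=0)
        topdx = np.take_along_axis(alldx, sel, axis=0)
        topdy = np.take_along_axis(alldy, sel, axis=0)

    # polish each candidate basin with shrinking local lattices
    best = topg.min(axis=0)
    for k in range(K):
        bg = topg[k].copy()
        bdx = topdx[k].copy()
        bdy = topdy[k].copy()
        sub = step
        for _ in range(refine_levels):
            sub = sub / 5.0
            cur_dx, cur_dy = bdx.copy(), bdy.copy()
            dloc = sub * np.arange(-5, 6)
            for ddx in dloc:
                for ddy in dloc:
                    if ddx == 0.0 and ddy == 0.0:
                        continue
                    dx = cur_dx + ddx
                    dy = cur_dy + ddy
                    de = interp(X + dx, Y + dy)
                    g2 = (dx * dx + dy * dy) / (dta * dta) + ((de - Dref) / dose_crit) ** 2
                    g2 = np.where(np.isnan(g2), np.inf, g2)
                    upd = g2 < bg
                    bg[upd] = g2[upd]
                    bdx[upd] = dx[upd]
                    bdy[upd] = dy[upd]
        best = np.minimum(best, bg)

    gam = np.sqrt(best)
    meta = {
        "normalization": norm,
        "ref_depth_gcm2": reference.depth,
        "eval_depth_gcm2": evaluated.depth,
        "method": "fast",
    }
    return _finish(reference, criteria, mask, gam, meta)


def gamma_2d_bruteforce(
    reference: DosePlane,
    evaluated: DosePlane,
    criteria: GammaCriteria,
    *,
    search_factor: float = 3.0,
    step: float | None = None,
    max_points: int = 200,
) -> GammaResult:
    """Exhaustive single-level gamma search — the test oracle.

    Evaluates the bilinear evaluated-plane surface on a dense offset
    lattice (default dta/50) within the search disk.  Refuses large grids:
    this path exists to check :func:`gamma_2d`, not to be fast.
    """
    ny, nx = reference.values.shape
    ney, nex = evaluated.values.shape
    if max(ny, nx, ney, nex) > max_points:
        raise InputError(f"brute-force oracle refuses grids larger than {max_points}")

    norm, mask, X, Y, Dref = _reference_points(reference, evaluated, criteria)
    dose_crit = criteria.dose_pct / 100.0 * norm
    dta = criteria.dta_mm
    h = step if step is not None else dta / 50.0
    offx, offy = _disk_offsets(h, search_factor * dta)

    # manual bilinear interpolation, chunked over offsets
    ex = evaluated.x_coords()
    ey = evaluated.y_coords()
    vals = evaluated.values
    sp = evaluated.spacing
    best = np.full(X.shape, np.inf)
    chunk = max(1, int(2_000_000 // max(1, X.size)))
    for i0 in range(0, len(offx), chunk):
        dx = offx[i0 : i0 + chunk][:, None]
        dy = offy[i0 : i0 + chunk][:, None]
        xq = X[None, :] + dx
        yq = Y[None, :] + dy
        fx = (xq - ex[0]) / sp
        fy = (yq - ey[0]) / sp
        valid = (fx >= 0) & (fx <= nex - 1) & (fy >= 0) & (fy <= ney - 1)
        ix = np.clip(np.floor(fx).astype(int), 0, nex - 2)
        iy = np.clip(np.floor(fy).astype(int), 0, ney - 2)
        tx = fx - ix
        ty = fy - iy
        de = (
            vals[iy, ix] * (1 - tx) * (1 - ty)
            + vals[iy, ix + 1] * tx * (1 - ty)
            + vals[iy + 1, ix] * (1 - tx) * ty
            + vals[iy + 1, ix + 1] * tx * ty
        )
        g2 = (dx * dx + dy * dy) / (dta * dta) + ((de - Dref[None, :]) / dose_crit) ** 2
        g2 = np.where(valid, g2, np.inf)
        best = np.minimum(best, g2.min(axis=0))

    gam = np.sqrt(best)
    meta = {
        "normalization": norm,
        "ref_depth_gcm2": reference.depth,
        "eval_depth_gcm2": evaluated.depth,
        "method": "bruteforce",
    }
    return _finish(reference, criteria, mask, gam, meta)


# --------------------------------------------------------------------------
# 2.5D gamma: depth search around the nominal plane
# --------------------------------------------------------------------------

@dataclass
class Gamma25dResult:
    """Per-depth gamma table plus the best depth (ties toward nominal)."""

    table: list                  # list of (offset_mm, GammaResult)
    best_offset_mm: float
    best_result: GammaResult
    nominal_depth: float         # g/cm^2

    @property
    def best_depth(self) -> float:
        return self.nominal_depth + self.best_offset_mm / MM_PER_GCM2

    @property
    def best_pass_rate(self) -> float:
        return self.best_result.pass_rate


def gamma_2p5d(
    measured: DosePlane,
    calc_source,
    nominal_depth: float,
    criteria: GammaCriteria,
    *,
    search_mm: float = 3.0,
    step_mm: float = 1.0,
    gamma_fn: Callable = gamma_2d,
) -> Gamma25dResult:
    """Compare one measured plane against calculated planes at shifted depths.

    ``calc_source`` is either a mapping ``offset_mm -> DosePlane`` covering
    every requested offset, or a callable ``depth_gcm2 -> DosePlane`` (e.g.
    a dose-engine closure).  Offsets run from -search_mm to +search_mm in
    steps of ``step_mm``; ``search_mm = 0`` degenerates to a single 2D
    comparison at the nominal depth.  The best depth maximizes the pass
    rate, ties broken toward the nominal depth (then toward shallower).
    """
    if step_mm <= 0:
        raise InputError("step_mm must be positive")
    if search_mm < 0:
        raise InputError("search_mm must be >= 0")
    k = int(round(search_mm / step_mm))
    offsets = [i * step_mm for i in range(-k, k + 1)] or [0.0]

    table = []
    for off in offsets:
        depth = nominal_depth + off / MM_PER_GCM2
        if callable(calc_source):
            plane = calc_source(depth)
        else:
            try:
                plane = calc_source[off]
            except KeyError as exc:
                raise InputError(f"no calculated plane for offset {off} mm") from exc
        if plane is None:
            raise InputError(f"calculated plane unavailable at offset {off} mm")
        res = gamma_fn(plane, measured, criteria)
        table.append((off, res))

    # max pass rate; ties -> smallest |offset|, then shallower (negative)
    best_off, best_res = min(
        table, key=lambda t: (-t[1].pass_rate, abs(t[0]), t[0])
    )
    return Gamma25dResult(table, best_off, best_res, nominal_depth)


# --------------------------------------------------------------------------
# 3D gamma on a stack of planes
# --------------------------------------------------------------------------

def _stack_arrays(planes: Sequence[DosePlane]):
    p0 = planes[0]
    for p in planes[1:]:
        if p.values.shape != p0.values.shape or p.spacing != p0.spacing \
                or p.origin_x != p0.origin_x or p.origin_y != p0.origin_y:
            raise InputError("all planes in a stack must share the lateral lattice")
    depths = np.array([p.depth for p in planes], dtype=float)
    if np.any(np.diff(depths) <= 0):
        raise InputError("stack depths must be strictly ascending")
    vol = np.stack([p.values for p in planes], axis=0)   # (nz, ny, nx)
    z_mm = depths * MM_PER_GCM2
    return vol, z_mm, depths


def gamma_3d(
    reference: Sequence[DosePlane],
    evaluated: Sequence[DosePlane],
    criteria: GammaCriteria,
    *,
    search_factor: float = 1.5,
    coarse_step: float | None = None,
    refine_levels: int = 2,
) -> GammaResult:
    """3D gamma over plane stacks: the search runs laterally and in depth.

    Depth distances are physical mm (10 mm per g/cm^2 of water).  With a
    single plane on both sides this falls through to :func:`gamma_2d`.
    The per-point map is returned as a (nz, ny, nx) volume.
    """
    reference = list(reference)
    evaluated = list(evaluated)
    if len(reference) == 1 and len(evaluated) == 1:
        res = gamma_2d(reference[0], evaluated[0], criteria)
        res.meta["note"] = "single-plane stacks: fell through to 2D gamma"
        return res
    if len(reference) < 2 or len(evaluated) < 2:
        raise InputError("3D gamma needs at least 2 planes per stack (or 1+1 for 2D)")

    rvol, rz, rdepths = _stack_arrays(reference)
    evol, ez, _ = _stack_arrays(evaluated)
    p0 = reference[0]
    e0 = evaluated[0]

    norm = criteria.normalization if criteria.normalization is not None else float(rvol.max())
    if norm <= 0:
        raise InputError("reference stack has no positive dose")
    thresh = criteria.threshold_pct / 100.0 * norm
    dose_crit = criteria.dose_pct / 100.0 * norm
    dta = criteria.dta_mm

    interp = RegularGridInterpolator(
        (ez, e0.y_coords(), e0.x_coords()), evol,
        method="linear", bounds_error=False, fill_value=np.nan,
    )

    Z, Y, X = np.meshgrid(rz, p0.y_coords(), p0.x_coords(), indexing="ij")
    inside = (
        (X >= e0.x_coords()[0]) & (X <= e0.x_coords()[-1])
        & (Y >= e0.y_coords()[0]) & (Y <= e0.y_coords()[-1])
        & (Z >= ez[0]) & (Z <= ez[-1])
    )
    mask = (rvol >= thresh) & inside
    Xm, Ym, Zm, Dm = X[mask], Y[mask], Z[mask], rvol[mask]

    step = coarse_step if coarse_step is not None else dta / 5.0
    radius = search_factor * dta
    n = int(math.floor(radius / step))
    d1 = step * np.arange(-n, n + 1)
    ddz, ddy, ddx = np.meshgrid(d1, d1, d1, indexing="ij")
    keep = np.sqrt(ddx**2 + ddy**2 + ddz**2) <= radius + 1e-12
    offs = np.stack([ddz[keep], ddy[keep], ddx[keep]], axis=1)

    best = np.full(Xm.shape, np.inf)
    bo = np.zeros((Xm.size, 3))
    for dz, dy, dx in offs:
        de = interp(np.stack([Zm + dz, Ym + dy, Xm + dx], axis=-1))
        g2 = (dx * dx + dy * dy + dz * dz) / (dta * dta) + ((de - Dm) / dose_crit) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        upd = g2 < best
        best[upd] = g2[upd]
        bo[upd] = (dz, dy, dx)

    for _ in range(refine_levels):
        sub = step / 4.0
        cur = bo.copy()
        dloc = sub * np.arange(-4, 5)
        for dz in dloc:
            for dy in dloc:
                for dx in dloc:
                    if dz == 0.0 and dy == 0.0 and dx == 0.0:
                        continue
                    oz = cur[:, 0] + dz
                    oy = cur[:, 1] + dy
                    ox = cur[:, 2] + dx
                    de = interp(np.stack([Zm + oz, Ym + oy, Xm + ox], axis=-1))
                    g2 = (ox * ox + oy * oy + oz * oz) / (dta * dta) + ((de - Dm) / dose_crit) ** 2
                    g2 = np.where(np.isnan(g2), np.inf, g2)
                    upd = g2 < best
                    best[upd] = g2[upd]
                    bo[upd, 0] = oz[upd]
                    bo[upd, 1] = oy[upd]
                    bo[upd, 2] = ox[upd]
        step = sub

    gam = np.sqrt(best)
    gmap = np.full(rvol.shape, np.nan)
    gmap[mask] = gam
    n_eval = int(mask.sum())
    rate = (
        100.0 * float(np.count_nonzero(gam <= 1.0 + 1e-12)) / n_eval
        if n_eval else float("nan")
    )
    meta = {
        "normalization": norm,
        "ref_depths_gcm2": list(rdepths),
        "method": "fast3d",
    }
    return GammaResult(gmap, rate, n_eval, criteria, meta)


# --------------------------------------------------------------------------
# QA decision cascade
# --------------------------------------------------------------------------

def qa_disposition(
    pass22: float,
    pass33: float,
    best25d: float | None = None,
    *,
    action_level: float = 90.0,
) -> QaDisposition:
    """Pass / review / fail cascade on gamma pass rates.

    Gate 1: 2%/2 mm rate >= action level -> pass.
    Gate 2: else review at 3%/3 mm; >= action level -> pass.
    Gate 3: else the 2.5D depth search; best rate >= action level -> pass,
    otherwise fail.  If the 2.5D rate is required but missing the status
    is ``review`` with an action-needed flag.
    """
    for name, v in (("pass22", pass22), ("pass33", pass33)):
        if not 0.0 <= v <= 100.0:
            raise InputError(f"{name} must be in [0, 100], got {v}")
    if best25d is not None and not 0.0 <= best25d <= 100.0:
        raise InputError(f"best25d must be in [0, 100], got {best25d}")

    ev = {"pass22": pass22, "pass33": pass33, "action_level": action_level}
    if best25d is not None:
        ev["best25d"] = best25d

    if pass22 >= action_level:
        return QaDisposition("pass", "2%/2mm", ev)
    if pass33 >= action_level:
        return QaDisposition("pass", "review:3%/3mm", ev)
    if best25d is None:
        ev["action_needed"] = "run the 2.5D depth search"
        return QaDisposition("review", "2.5D-required", ev)
    if best25d >= action_level:
        return QaDisposition("pass", "review:2.5D", ev)
    return QaDisposition("fail", "2.5D", ev)
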