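"""Analytical beam data for a scanned proton pencil beam.

This module holds the three ingredients of the independent dose model:

* an analytical Bragg curve (integral depth dose per MU) in the
  parabolic-cylinder-function closed form, with a low-energy tail term,
* a power-law range-energy calibration ``R = alpha * E**p``,
* a depth-dependent lateral kernel built from two Gaussians (multiple
  Coulomb scattering) plus a normalizable heavy-tailed Cauchy-Lorentz
  component (large-angle / nuclear halo).

Depths and ranges are water-equivalent and expressed in g/cm^2 (water
density 1 g/cm^3, so 1 mm of water = 0.1 g/cm^2).  Lateral distances are
in mm at the isocenter plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import optimize, special

__all__ = [
    "BortfeldParams",
    "DepthDoseCurve",
    "LateralKernelParams",
    "MachineConfig",
    "BeamLibrary",
    "BortfeldFitResult",
    "bortfeld_idd",
    "fit_bortfeld",
    "calibrate_range_energy",
    "range_from_energy",
    "energy_from_range",
    "lateral_kernel",
    "kernel_mass_within",
    "kernel_truncation_radius",
]

# Slowing-down constants of the analytical Bragg model (water).
_BETA = 0.012   # 1/(g/cm^2), linear correction to the fluence reduction
_GAMMA = 0.6    # fraction of locally absorbed energy from nuclear interactions


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class InputError(ValueError):
    """Raised when an operation receives out-of-contract input."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BortfeldParams:
    """Parameters of the analytical Bragg curve for one nominal energy.

    Attributes
    ----------
    r0 : float
        Range in water (g/cm^2); depth at which the primary model terminates.
    sigma : float
        Range-straggling width (g/cm^2).
    epsilon : float
        Low-energy tail fraction (dimensionless, ``0 <= epsilon < 1``).
    phi : float
        Fluence/dose scale (dose * cm^2 per MU).
    p : float
        Range-energy exponent (dimensionless, in (1.5, 2.1)).
    alpha : float
        Range-energy coefficient (g/cm^2 / MeV**p).
    energy_mev : float
        Nominal energy label (MeV), carried for bookkeeping.
    """

    r0: float
    sigma: float
    epsilon: float
    phi: float
    p: float
    alpha: float
    energy_mev: float = float("nan")

    def validate(self) -> "BortfeldParams":
        if not self.r0 > 0:
            raise ValidationError(f"r0 must be > 0, got {self.r0}")
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValidationError(f"epsilon must be in [0, 1), got {self.epsilon}")
        if not self.phi > 0:
            raise ValidationError(f"phi must be > 0, got {self.phi}")
        if not 1.5 < self.p < 2.1:
            raise ValidationError(f"p must be in (1.5, 2.1), got {self.p}")
        if not self.alpha > 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        return self


@dataclass(frozen=True)
class DepthDoseCurve:
    """Integral depth dose sampled on an ascending depth grid."""

    depths: np.ndarray     # g/cm^2, strictly increasing
    values: np.ndarray     # dose*cm^2 per MU, >= 0
    energy_label: float = float("nan")   # MeV

    def __post_init__(self):
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.depths.shape != self.values.shape or self.depths.ndim != 1:
            raise ValidationError("depths and values must be 1-D of equal length")
        if len(self.depths) and not np.all(np.diff(self.depths) > 0):
            raise ValidationError("depths must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("values must be non-negative")


@dataclass(frozen=True)
class LateralKernelParams:
    """Depth-dependent lateral spread of a single pencil beam.

    ``sigma1``, ``sigma2`` (mm) and the Cauchy-Lorentz scale ``s`` (mm) are
    low-order polynomials of the water-equivalent depth ``z`` (g/cm^2),
    stored as ascending coefficient tuples.  ``w2`` and ``wcl`` are the
    (possibly depth-dependent) weights of the second Gaussian and the
    Cauchy-Lorentz component.  The in-air spot fluence at the phantom
    surface is the double Gaussian (sigma_air1, sigma_air2, w_air); by
    convention the surface values of sigma1/sigma2/w2 equal it.
    """

    sigma1_coef: tuple
    sigma2_coef: tuple
    s_coef: tuple
    w2_coef: tuple = (0.1,)
    wcl_coef: tuple = (0.05,)
    sigma_air1: float = float("nan")
    sigma_air2: float = float("nan")
    w_air: float = float("nan")

    def sigma1(self, z):
        return npoly.polyval(z, self.sigma1_coef)

    def sigma2(self, z):
        return npoly.polyval(z, self.sigma2_coef)

    def s(self, z):
        return npoly.polyval(z, self.s_coef)

    def w2(self, z):
        return np.clip(npoly.polyval(z, self.w2_coef), 0.0, 1.0)

    def wcl(self, z):
        return np.clip(npoly.polyval(z, self.wcl_coef), 0.0, 1.0)

    def validate(self, zmax: float = 35.0, n: int = 64) -> "LateralKernelParams":
        z = np.linspace(0.0, zmax, n)
        s1, s2, s = self.sigma1(z), self.sigma2(z), self.s(z)
        if np.any(s1 <= 0) or np.any(s2 <= 0) or np.any(s <= 0):
            raise ValidationError("sigma1, sigma2 and s must stay positive on [0, zmax]")
        if np.any(s2 < s1 - 1e-12):
            raise ValidationError("sigma2 must dominate sigma1 at every depth")
        w2 = npoly.polyval(z, self.w2_coef)
        wcl = npoly.polyval(z, self.wcl_coef)
        if np.any(w2 < -1e-12) or np.any(w2 > 1 + 1e-12):
            raise ValidationError("w2 must lie in [0, 1]")
        if np.any(wcl < -1e-12) or np.any(wcl > 1 + 1e-12):
            raise ValidationError("wcl must lie in [0, 1]")
        return self


@dataclass(frozen=True)
class MachineConfig:
    """Delivery-machine description used throughout the toolkit."""

    energies_mev: tuple            # ascending nominal energies
    ranges_gcm2: tuple             # matching nominal ranges in water
    max_field_mm: float = 300.0    # lateral field limit at isocenter (30 x 30 cm)
    rs_wet_gcm2: float = 3.7       # range-shifter water-equivalent thickness
    rs_physical_cm: float = 6.7    # physical thickness of the ABS shifter
    default_spacing_mm: float = 1.0

    def __post_init__(self):
        e = np.asarray(self.energies_mev, dtype=float)
        r = np.asarray(self.ranges_gcm2, dtype=float)
        if e.shape != r.shape or e.ndim != 1 or len(e) == 0:
            raise ValidationError("energies and ranges must be matching 1-D sequences")
        if len(e) > 1 and (np.any(np.diff(e) <= 0) or np.any(np.diff(r) <= 0)):
            raise ValidationError("energies and ranges must be strictly ascending")
        if not self.max_field_mm > 0:
            raise ValidationError("max_field_mm must be > 0")
        if self.rs_wet_gcm2 < 0:
            raise ValidationError("rs_wet_gcm2 must be >= 0")
        object.__setattr__(self, "energies_mev", tuple(float(x) for x in e))
        object.__setattr__(self, "ranges_gcm2", tuple(float(x) for x in r))

    @property
    def n_energies(self) -> int:
        return len(self.energies_mev)


@dataclass(frozen=True)
class BeamLibrary:
    """Per-energy Bragg and lateral-kernel parameters plus the machine model."""

    machine: MachineConfig
    bragg: tuple            # BortfeldParams per energy (ascending)
    kernels: tuple          # LateralKernelParams per energy
    schema_version: str = "1"

    def __post_init__(self):
        if not (len(self.bragg) == len(self.kernels) == self.machine.n_energies):
            raise ValidationError("library arrays must match the machine energy list")

    def idd(self, energy_index: int, z):
        return bortfeld_idd(z, self.bragg[energy_index])

    def kernel_params(self, energy_index: int) -> LateralKernelParams:
        return self.kernels[energy_index]

    @property
    def max_range(self) -> float:
        return max(p.r0 for p in self.bragg)


# --------------------------------------------------------------------------
# Bragg curve
# --------------------------------------------------------------------------

def _conv_powerlaw(a: float, zeta: np.ndarray) -> np.ndarray:
    """Gaussian-smeared truncated power law, in straggling-width units.

    Returns ``g_a(zeta)`` such that the convolution of ``xi_+**a`` with a
    Gaussian of width sigma equals ``sigma**a * g_a(xi / sigma)``.
    """
    d = special.pbdv(-(a + 1.0), -zeta)[0]
    return special.gamma(a + 1.0) / math.sqrt(2.0 * math.pi) * np.exp(-zeta * zeta / 4.0) * d


def bortfeld_idd(z, params: BortfeldParams, tail_fn=None):
    """Integral depth dose per MU at water-equivalent depth ``z`` (g/cm^2).

    The closed analytical form: a power-law slowing-down term plus a
    buildup term carrying nuclear-interaction and low-energy-tail
    contributions (weight ``epsilon``), both convolved with a Gaussian
    range-straggling distribution of width ``sigma``.  The convolution is
    expressed through parabolic cylinder functions near the peak and
    reduces to the bare power law far upstream.

    ``tail_fn(z, params)``, if given, is added on top — the hook for an
    alternative "modified" tail term.
    """
    params.validate()
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise InputError("depth must be non-negative")
    r0, sig, eps, p = params.r0, params.sigma, params.epsilon, params.p
    a = 1.0 / p - 1.0
    c2 = _BETA + _GAMMA * _BETA * p + eps * p / r0
    pref = params.phi / (p * params.alpha ** (1.0 / p) * (1.0 + _BETA * r0))

    xi = r0 - z
    zeta = xi / sig
    out = np.zeros(np.shape(zeta), dtype=float)

    # far upstream: convolution is indistinguishable from the bare power law
    up = zeta >= 10.0
    if np.any(up):
        x = np.atleast_1d(xi)[np.atleast_1d(up)]
        out_up = x ** a + c2 * x ** (a + 1.0)
        if out.ndim == 0:
            out = np.asarray(out_up[0])
        else:
            out[up] = out_up
    # peak region: parabolic-cylinder closed form
    mid = (zeta < 10.0) & (zeta > -10.0)
    if np.any(mid):
        zm = np.atleast_1d(zeta)[np.atleast_1d(mid)]
        val = sig ** a * _conv_powerlaw(a, zm) + c2 * sig ** (a + 1.0) * _conv_powerlaw(a + 1.0, zm)
        if out.ndim == 0:
            out = np.asarray(val[0])
        else:
            out[mid] = val
    # z > r0 + 10 sigma: extinct (below 1e-6 of peak analytically)

    out = pref * out
    if tail_fn is not None:
        out = out + tail_fn(z, params)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# range-energy law
# --------------------------------------------------------------------------

def calibrate_range_energy(points: Sequence[tuple]) -> tuple:
    """Fit ``R = alpha * E**p`` to (energy MeV, range g/cm^2) pairs.

    Two points give the exact solution; more points a log-log least
    squares fit.  Returns ``(alpha, p)``.
    """
    pts = [(float(e), float(r)) for e, r in points]
    if len(pts) < 2:
        raise InputError("need at least two calibration points")
    e = np.array([q[0] for q in pts])
    r = np.array([q[1] for q in pts])
    if np.any(e <= 0) or np.any(r <= 0):
        raise InputError("energies and ranges must be positive")
    if len(pts) == 2:
        p = math.log(r[1] / r[0]) / math.log(e[1] / e[0])
        alpha = r[0] / e[0] ** p
    else:
        p, la = np.polyfit(np.log(e), np.log(r), 1)
        alpha = math.exp(la)
    return float(alpha), float(p)


def range_from_energy(energy_mev, alpha: float, p: float, *, span: tuple | None = None):
    """Range in water (g/cm^2) from the power law; warns outside ``span``."""
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e <= 0):
        raise InputError("energy must be positive")
    if span is not None and (np.any(e < span[0]) or np.any(e > span[1])):
        import warnings

        warnings.warn("energy outside the configured machine span", stacklevel=2)
    out = alpha * e ** p
    return out if out.ndim else float(out)


def energy_from_range(range_gcm2, alpha: float, p: float):
    """Inverse of :func:`range_from_energy`."""
    r = np.asarray(range_gcm2, dtype=float)
    if np.any(r <= 0):
        raise InputError("range must be positive")
    out = (r / alpha) ** (1.0 / p)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# lateral kernel
# --------------------------------------------------------------------------

def _gauss2d(r, sigma):
    return np.exp(-(r * r) / (2.0 * sigma * sigma)) / (2.0 * math.pi * sigma * sigma)


def _cauchy_lorentz2d(r, s):
    # normalizable radial heavy-tail: integrates to 1 over the plane
    u = r / s
    return 1.0 / (math.pi * s * s) / (1.0 + u * u) ** 2


def lateral_kernel(r, z, params: LateralKernelParams):
    """Areal density (mm^-2) of the pencil-beam lateral spread at depth z.

    Two Gaussians (weights ``1-w2`` and ``w2``) plus a Cauchy-Lorentz
    heavy tail of weight ``wcl``; the composition integrates to exactly 1
    over the plane for valid parameters.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InputError("radius must be non-negative")
    s1 = params.sigma1(z)
    s2 = params.sigma2(z)
    s = params.s(z)
    if np.any(np.asarray(s1) <= 0) or np.any(np.asarray(s2) <= 0) or np.any(np.asarray(s) <= 0):
        raise ValidationError("kernel widths must be positive at the requested depth")
    w2 = params.w2(z)
    wcl = params.wcl(z)
    gauss = (1.0 - w2) * _gauss2d(r, s1) + w2 * _gauss2d(r, s2)
    out = (1.0 - wcl) * gauss + wcl * _cauchy_lorentz2d(r, s)
    return out if np.ndim(out) else float(out)


def kernel_mass_within(radius: float, z, params: LateralKernelParams) -> float:
    """Closed-form plane integral of the kernel inside ``r <= radius``."""
    s1 = float(params.sigma1(z))
    s2 = float(params.sigma2(z))
    s = float(params.s(z))
    w2 = float(params.w2(z))
    wcl = float(params.wcl(z))
    g1 = 1.0 - math.exp(-(radius * radius) / (2.0 * s1 * s1))
    g2 = 1.0 - math.exp(-(radius * radius) / (2.0 * s2 * s2))
    cl = 1.0 - 1.0 / (1.0 + (radius / s) ** 2)
    return (1.0 - wcl) * ((1.0 - w2) * g1 + w2 * g2) + wcl * cl


def kernel_truncation_radius(z, params: LateralKernelParams) -> float:
    """Bounded-support evaluation radius: 8*sigma2 + 5*s."""
    return 8.0 * float(params.sigma2(z)) + 5.0 * float(params.s(z))


# --------------------------------------------------------------------------
# simultaneous Bragg-curve fitting
# --------------------------------------------------------------------------

@dataclass
class BortfeldFitResult:
    """Outcome of a (simultaneous) Bragg-curve fit."""

    params: list                 # BortfeldParams per curve
    alpha: float
    p: float
    residual_norms: list = field(default_factory=list)
    converged: bool = True
    message: str = ""


def _distal_falloff_depth(curve: DepthDoseCurve, level: float = 0.8) -> float:
    """Depth where the curve drops to ``level`` of its peak on the distal side."""
    v = curve.values
    d = curve.depths
    ipk = int(np.argmax(v))
    target = level * v[ipk]
    distal_v = v[ipk:]
    distal_d = d[ipk:]
    below = np.nonzero(distal_v <= target)[0]
    if len(below) == 0:
        return float(distal_d[-1])
    j = below[0]
    if j == 0:
        return float(distal_d[0])
    # linear interpolation between the bracketing samples
    v0, v1 = distal_v[j - 1], distal_v[j]
    d0, d1 = distal_d[j - 1], distal_d[j]
    t = (target - v0) / (v1 - v0) if v1 != v0 else 0.0
    return float(d0 + t * (d1 - d0))


def fit_bortfeld(curves: Sequence[DepthDoseCurve], share=("alpha", "p")) -> BortfeldFitResult:
    """Fit the analytical Bragg model to measured depth-dose curves.

    With the default ``share=("alpha", "p")`` the range-energy law is the
    coupling: a single ``(alpha, p)`` pair is fitted across all curves and
    each curve's range is tied to its energy label through
    ``R0 = alpha * E**p``; sigma, epsilon and phi stay per-curve.  With
    ``share=()`` every curve is fitted independently with a free range.

    Deterministic: initialization is derived from the data (distal-80%
    range estimate, sigma = 1% of R0, epsilon = 0.1), no randomness.
    """
    curves = list(curves)
    share = tuple(share) if share else ()
    if share and share != ("alpha", "p"):
        raise InputError("only share=('alpha','p') or share=() are supported")
    if len(curves) == 0:
        raise InputError("no curves given")
    if share and len(curves) < 2:
        raise InputError("shared-parameter fitting requires at least 2 curves")
    for c in curves:
        if len(c.depths) < 6:
            raise InputError("each curve needs at least 6 samples")

    r0_init = np.array([_distal_falloff_depth(c) for c in curves])
    for c, r0 in zip(curves, r0_init):
        if c.depths[0] > 0.6 * r0 or c.depths[-1] < 0.95 * r0:
            raise InputError(
                "each curve must sample both the entrance and the peak region"
            )
    energies = np.array([c.energy_label for c in curves])
    if share and (np.any(~np.isfinite(energies)) or np.any(energies <= 0)):
        raise InputError("shared fitting requires positive energy labels")

    # initial range-energy law from the per-curve range estimates
    if len(curves) >= 2 and np.all(np.isfinite(energies)) and np.all(energies > 0):
        p0, la0 = np.polyfit(np.log(energies), np.log(r0_init), 1)
        p0 = float(np.clip(p0, 1.55, 2.05))
        alpha0 = float(np.exp(la0))
    else:
        p0, alpha0 = 1.77, 0.0022

    sig0 = 0.01 * r0_init
    eps0 = np.full(len(curves), 0.1)
    phi0 = np.ones(len(curves))
    # scale phi so the model matches the entrance dose
    for i, c in enumerate(curves):
        trial = BortfeldParams(
            r0=float(r0_init[i]), sigma=float(sig0[i]), epsilon=0.1, phi=1.0,
            p=p0, alpha=alpha0, energy_mev=float(energies[i]),
        )
        m = bortfeld_idd(c.depths[0], trial)
        if m > 0:
            phi0[i] = float(c.values[0] / m)

    n = len(curves)

    if share:
        # x = [log alpha, p, (log sigma_i, epsilon_i, log phi_i) * n]
        x0 = np.concatenate([[math.log(alpha0), p0],
                             np.ravel(np.column_stack([np.log(sig0), eps0, np.log(phi0)]))])
        lo = np.concatenate([[-20.0, 1.501], np.tile([-10.0, 0.0, -20.0], n)])
        hi = np.concatenate([[5.0, 2.099], np.tile([5.0, 0.9, 20.0], n)])

        def unpack(x):
            alpha, p = math.exp(x[0]), x[1]
            rest = x[2:].reshape(n, 3)
            out = []
            for i in range(n):
                r0 = alpha * energies[i] ** p
                out.append(BortfeldParams(
                    r0=r0, sigma=math.exp(rest[i, 0]), epsilon=rest[i, 1],
                    phi=math.exp(rest[i, 2]), p=p, alpha=alpha,
                    energy_mev=float(energies[i]),
                ))
            return out

        def resid(x):
            prm = unpack(x)
            parts = []
            for c, q in zip(curves, prm):
                scale = float(np.max(c.values))
                parts.append((bortfeld_idd(c.depths, q) - c.values) / scale)
            return np.concatenate(parts)

        sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000)
        fitted = unpack(sol.x)
        alpha_out, p_out = fitted[0].alpha, fitted[0].p
    else:
        fitted = []
        oks = []
        for i, c in enumerate(curves):
            x0 = np.array([math.log(r0_init[i]), math.log(sig0[i]), eps0[i], math.log(phi0[i])])
            lo = np.array([-10.0, -10.0, 0.0, -20.0])
            hi = np.array([5.0, 5.0, 0.9, 20.0])
            e_i = float(energies[i]) if np.isfinite(energies[i]) else 100.0

            def unpack1(x):
                r0 = math.exp(x[0])
                return BortfeldParams(
                    r0=r0, sigma=math.exp(x[1]), epsilon=x[2], phi=math.exp(x[3]),
                    p=p0, alpha=r0 / e_i ** p0, energy_mev=e_i,
                )

            def resid1(x, c=c, unpack1=unpack1):
                scale = float(np.max(c.values))
                return (bortfeld_idd(c.depths, unpack1(x)) - c.values) / scale

            sol = optimize.least_squares(resid1, x0, bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
            fitted.append(unpack1(sol.x))
            oks.append(sol.success)
        alpha_out = float(np.nan)
        p_out = p0
        sol_success = all(oks)

    norms = []
    for c, q in zip(curves, fitted):
        res = bortfeld_idd(c.depths, q) - c.values
        norms.append(float(np.linalg.norm(res) / np.linalg.norm(c.values)))

    converged = bool(sol.success) if share else sol_success
    return BortfeldFitResult(
        params=fitted, alpha=float(alpha_out), p=float(p_out),
        residual_norms=norms, converged=converged,
        message="" if converged else "optimizer did not report convergence",
    )
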