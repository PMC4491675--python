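import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from spotqa.beam_model import (
    BortfeldParams,
    DepthDoseCurve,
    bortfeld_idd,
    calibrate_range_energy,
    energy_from_range,
)
from spotqa.dose_engine import DosePlane, Field, GridSpec, PhantomGeometry, Spot
from spotqa.synthetic_data import DEFAULT_CALIBRATION_POINTS, make_beam_library


@pytest.fixture(scope="session")
def small_library():
    """10 energies spanning 8-16 g/cm^2 — cheap but realistic."""
    return make_beam_library(n_energies=10, range_span=(8.0, 16.0))


@pytest.fixture(scope="session")
def range_energy_law():
    return calibrate_range_energy(DEFAULT_CALIBRATION_POINTS)


@pytest.fixture(scope="session")
def bragg_truth(range_energy_law):
    """Seven ground-truth Bragg parameter sets spanning 5-30 g/cm^2."""
    alpha, p = range_energy_law
    ranges = np.linspace(5.0, 30.0, 7)
    energies = energy_from_range(ranges, alpha, p)
    return [
        BortfeldParams(
            r0=float(r0), sigma=0.08 + 0.012 * float(r0), epsilon=0.1,
            phi=1.0 + 0.01 * float(r0), p=p, alpha=alpha, energy_mev=float(e),
        )
        for e, r0 in zip(energies, ranges)
    ]


@pytest.fixture(scope="session")
def bragg_curves(bragg_truth):
    curves = []
    for prm in bragg_truth:
        z = np.linspace(0.2, prm.r0 + 1.0, 80)
        curves.append(DepthDoseCurve(z, bortfeld_idd(z, prm), prm.energy_mev))
    return curves


@pytest.fixture
def single_spot_field():
    return Field([Spot(5, 0.0, 0.0, 1.0)], field_id="single")


@pytest.fixture
def phantom():
    return PhantomGeometry()


def smooth_random_plane(rng, n, spacing=2.0, smooth_px=4.0):
    """A dose-like smooth random plane normalized to [0, 1]."""
    pad = int(3 * smooth_px)
    a = gaussian_filter(rng.random((n + 2 * pad, n + 2 * pad)), smooth_px)
    a = a[pad : pad + n, pad : pad + n]
    a = (a - a.min()) / (a.max() - a.min() + 1e-12)
    return DosePlane(a, 0.0, 0.0, spacing, 5.0)


def gaussian_bump_plane(n=41, spacing=2.0, sigma_mm=10.0, center=(0.0, 0.0), depth=5.0):
    half = (n - 1) / 2.0 * spacing
    x = np.linspace(-half, half, n)
    X, Y = np.meshgrid(x, x)
    v = np.exp(-((X - center[0]) ** 2 + (Y - center[1]) ** 2) / (2 * sigma_mm**2))
    return DosePlane(v, -half, -half, spacing, depth)
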