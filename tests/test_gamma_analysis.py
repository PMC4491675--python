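import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import RegularGridInterpolator

from conftest import gaussian_bump_plane, smooth_random_plane
from spotqa.beam_model import InputError, ValidationError
from spotqa.dose_engine import DosePlane
from spotqa.gamma_analysis import (
    GammaCriteria,
    _gamma_gradient_scale,
    gamma_2d,
    gamma_2d_bruteforce,
    gamma_2p5d,
    gamma_3d,
    point_dose_difference,
    qa_disposition,
)

CRIT33 = GammaCriteria(3.0, 3.0, 10.0)


class TestPointDose:
    def test_identity(self):
        assert point_dose_difference(1.0, 1.0, 1.0) == 0.0

    def test_arithmetic(self):
        assert point_dose_difference(1.03, 1.0, 1.0) == pytest.approx(3.0)

    def test_normalization_scaling(self):
        assert point_dose_difference(0.97, 1.0, 2.0) == pytest.approx(-1.5)

    def test_zero_norm_rejected(self):
        with pytest.raises(InputError):
            point_dose_difference(1.0, 1.0, 0.0)

    @given(
        m=st.floats(0.0, 10.0), c=st.floats(0.0, 10.0),
        n=st.floats(0.1, 10.0), k=st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, m, c, n, k):
        a = point_dose_difference(m, c, n)
        b = point_dose_difference(k * m, k * c, k * n)
        assert b == pytest.approx(a, abs=1e-9)


class TestGamma2dClosedForms:
    def test_identity(self):
        rng = np.random.default_rng(1)
        ref = smooth_random_plane(rng, 25)
        res = gamma_2d(ref, ref, CRIT33)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_map) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_offset_45(self):
        ref = DosePlane(np.ones((15, 15)), 0, 0, 2.0, 5.0)
        ev = DosePlane(np.full((15, 15), 1.045), 0, 0, 2.0, 5.0)
        res = gamma_2d(ref, ev, CRIT33)
        assert res.pass_rate == 0.0
        g = res.gamma_map[~np.isnan(res.gamma_map)]
        assert np.allclose(g, 1.5, atol=1e-9)

    def test_uniform_offset_boundary_passes(self):
        ref = DosePlane(np.ones((15, 15)), 0, 0, 2.0, 5.0)
        ev = DosePlane(np.full((15, 15), 1.03), 0, 0, 2.0, 5.0)
        res = gamma_2d(ref, ev, CRIT33)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_map) == pytest.approx(1.0, abs=1e-9)

    def test_shifted_bump_passes_with_dta(self):
        ref = gaussian_bump_plane(41, 2.0, 10.0, (0.0, 0.0))
        ev = gaussian_bump_plane(41, 2.0, 10.0, (2.0, 0.0))
        res = gamma_2d(ref, ev, CRIT33)
        assert res.pass_rate == 100.0
        assert res.max_gamma <= 2.0 / 3.0 + 0.05

    def test_threshold_exclusion(self):
        v = np.ones((10, 10))
        v[:5] = 0.05   # below the 10% cutoff
        ref = DosePlane(v, 0, 0, 2.0, 5.0)
        res = gamma_2d(ref, ref, CRIT33)
        assert res.n_evaluated == 50

    def test_all_below_threshold_flagged(self):
        ref = DosePlane(np.full((8, 8), 0.05), 0, 0, 2.0, 5.0,)
        crit = GammaCriteria(3.0, 3.0, 10.0, normalization=1.0)
        res = gamma_2d(ref, ref, crit)
        assert res.n_evaluated == 0
        assert "warning" in res.meta

    def test_disjoint_grids_rejected(self):
        a = DosePlane(np.ones((5, 5)), 0, 0, 1.0, 5.0)
        b = DosePlane(np.ones((5, 5)), 100.0, 100.0, 1.0, 5.0)
        with pytest.raises(InputError):
            gamma_2d(a, b, CRIT33)

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        ref = smooth_random_plane(rng, 20)
        ev = DosePlane(ref.values * 1.02, 0, 0, ref.spacing, 5.0)
        r1 = gamma_2d(ref, ev, GammaCriteria(3, 3, 10, normalization=1.0))
        ref2 = DosePlane(ref.values * 7.0, 0, 0, ref.spacing, 5.0)
        ev2 = DosePlane(ev.values * 7.0, 0, 0, ref.spacing, 5.0)
        r2 = gamma_2d(ref2, ev2, GammaCriteria(3, 3, 10, normalization=7.0))
        assert np.allclose(r1.gamma_map, r2.gamma_map, atol=1e-9, equal_nan=True)

    def test_criteria_validation(self):
        with pytest.raises(ValidationError):
            GammaCriteria(dose_pct=-3.0)
        with pytest.raises(ValidationError):
            GammaCriteria(threshold_pct=100.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_fast_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 28))
        ref = smooth_random_plane(rng, n)
        pert = smooth_random_plane(rng, n).values
        ev = DosePlane(
            np.clip(ref.values * 1.01 + 0.025 * (pert - 0.5), 0, None),
            0, 0, ref.spacing, 5.0,
        )
        gs = _gamma_gradient_scale(ev, 0.03 * ref.values.max())
        bstep = min(3.0 / 50.0, 0.03 / gs)
        fast = gamma_2d(ref, ev, CRIT33, search_factor=1.0)
        brute = gamma_2d_bruteforce(ref, ev, CRIT33, search_factor=1.0, step=bstep)
        assert np.nanmax(np.abs(fast.gamma_map - brute.gamma_map)) <= 0.02

    def test_bruteforce_identity(self):
        rng = np.random.default_rng(5)
        ref = smooth_random_plane(rng, 20)
        res = gamma_2d_bruteforce(ref, ref, CRIT33)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_map) == pytest.approx(0.0, abs=1e-12)

    def test_bruteforce_uniform_boundary(self):
        ref = DosePlane(np.ones((12, 12)), 0, 0, 2.0, 5.0)
        ev = DosePlane(np.full((12, 12), 1.03), 0, 0, 2.0, 5.0)
        res = gamma_2d_bruteforce(ref, ev, CRIT33)
        assert res.pass_rate == 100.0

    def test_bruteforce_refuses_large_grids(self):
        big = DosePlane(np.ones((250, 250)), 0, 0, 1.0, 5.0)
        with pytest.raises(InputError):
            gamma_2d_bruteforce(big, big, CRIT33)


class TestCriteriaMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_loosening_never_decreases_pass_rate(self, seed):
        rng = np.random.default_rng(100 + seed)
        ref = smooth_random_plane(rng, 22)
        ev = DosePlane(
            np.clip(ref.values + rng.normal(0, 0.02, ref.values.shape), 0, None),
            0, 0, ref.spacing, 5.0,
        )
        tight = gamma_2d(ref, ev, GammaCriteria(2.0, 2.0, 10.0)).pass_rate
        loose_d = gamma_2d(ref, ev, GammaCriteria(3.0, 2.0, 10.0)).pass_rate
        loose_b = gamma_2d(ref, ev, GammaCriteria(3.0, 3.0, 10.0)).pass_rate
        assert loose_d >= tight - 1e-9
        assert loose_b >= loose_d - 1e-9


def _distal_gradient_planes(small_library):
    """Calculated planes for a single-energy layer near its distal edge."""
    from spotqa.dose_engine import Field, GridSpec, PhantomGeometry, Spot, compute_dose_plane

    ei = 5
    prm = small_library.bragg[ei]
    spots = [
        Spot(ei, float(x), float(y), 1.0)
        for x in np.arange(-20, 21, 5.0)
        for y in np.arange(-20, 21, 5.0)
    ]
    fld = Field(spots)
    grid = GridSpec(-30.0, -30.0, 2.0, 31, 31)
    nominal = prm.r0 + 0.1   # inside the distal falloff: steep depth gradient
    phantom = PhantomGeometry()

    def calc(depth):
        return compute_dose_plane(small_library, fld, phantom, depth, grid)

    return calc, nominal


class TestGamma25d:
    def test_identity_at_nominal(self, small_library):
        calc, nominal = _distal_gradient_planes(small_library)
        measured = calc(nominal)
        res = gamma_2p5d(measured, calc, nominal, CRIT33)
        assert res.best_offset_mm == 0.0
        assert res.best_pass_rate == 100.0

    def test_recovers_injected_depth_offset(self, small_library):
        calc, nominal = _distal_gradient_planes(small_library)
        measured = calc(nominal - 0.2)   # 2 mm shallower
        res = gamma_2p5d(measured, calc, nominal, CRIT33)
        assert res.best_offset_mm == -2.0
        assert res.best_pass_rate == 100.0
        at_nominal = dict(res.table)[0.0].pass_rate
        assert at_nominal < 100.0

    @pytest.mark.parametrize("k", [-1, 0, 1])
    def test_recovers_k_step_offsets(self, small_library, k):
        calc, nominal = _distal_gradient_planes(small_library)
        measured = calc(nominal + 0.1 * k)
        res = gamma_2p5d(measured, calc, nominal, CRIT33)
        assert res.best_offset_mm == pytest.approx(1.0 * k)

    def test_zero_search_degenerates_to_2d(self, small_library):
        calc, nominal = _distal_gradient_planes(small_library)
        measured = calc(nominal)
        res = gamma_2p5d(measured, calc, nominal, CRIT33, search_mm=0.0)
        assert len(res.table) == 1
        assert res.best_offset_mm == 0.0

    def test_mapping_source_and_missing_offset(self, small_library):
        calc, nominal = _distal_gradient_planes(small_library)
        planes = {off: calc(nominal + off / 10.0) for off in (-1.0, 0.0, 1.0)}
        res = gamma_2p5d(planes[0.0], planes, nominal, CRIT33, search_mm=1.0)
        assert res.best_offset_mm == 0.0
        with pytest.raises(InputError):
            gamma_2p5d(planes[0.0], planes, nominal, CRIT33, search_mm=3.0)


def _bump_stack(center, n=25, spacing=2.0, depths=(4.8, 5.0, 5.2, 5.4, 5.6)):
    """Smooth 3D stack: lateral bump whose amplitude varies with depth."""
    planes = []
    for i, d in enumerate(depths):
        amp = 1.0 - 0.15 * i
        p = gaussian_bump_plane(n, spacing, 12.0, center, depth=d)
        planes.append(DosePlane(p.values * amp, p.origin_x, p.origin_y, spacing, d))
    return planes


def _gamma3d_bruteforce(reference, evaluated, criteria, step=0.1, radius_factor=1.5):
    """Tiny exhaustive 3D oracle for small stacks."""
    from spotqa.gamma_analysis import MM_PER_GCM2

    rvol = np.stack([p.values for p in reference])
    evol = np.stack([p.values for p in evaluated])
    rz = np.array([p.depth for p in reference]) * MM_PER_GCM2
    ez = np.array([p.depth for p in evaluated]) * MM_PER_GCM2
    p0, e0 = reference[0], evaluated[0]
    norm = float(rvol.max())
    thresh = criteria.threshold_pct / 100 * norm
    crit = criteria.dose_pct / 100 * norm
    dta = criteria.dta_mm
    interp = RegularGridInterpolator(
        (ez, e0.y_coords(), e0.x_coords()), evol,
        bounds_error=False, fill_value=np.nan,
    )
    Z, Y, X = np.meshgrid(rz, p0.y_coords(), p0.x_coords(), indexing="ij")
    mask = rvol >= thresh
    pts = np.stack([Z[mask], Y[mask], X[mask]], axis=1)
    D = rvol[mask]
    n = int(radius_factor * dta / step)
    d1 = step * np.arange(-n, n + 1)
    best = np.full(len(pts), np.inf)
    for dz in d1:
        for dy in d1:
            for dx in d1:
                rr = dx * dx + dy * dy + dz * dz
                if rr > (radius_factor * dta) ** 2:
                    continue
                de = interp(pts + np.array([dz, dy, dx]))
                g2 = rr / dta**2 + ((de - D) / crit) ** 2
                g2 = np.where(np.isnan(g2), np.inf, g2)
                best = np.minimum(best, g2)
    gam = np.sqrt(best)
    rate = 100.0 * np.count_nonzero(gam <= 1 + 1e-12) / len(gam)
    return gam, rate


class TestGamma3d:
    def test_identity(self):
        stack = _bump_stack((0.0, 0.0))
        res = gamma_3d(stack, stack, CRIT33)
        assert res.pass_rate == 100.0

    def test_depth_slice_shift_absorbed(self):
        ref = _bump_stack((0.0, 0.0), depths=(4.8, 5.0, 5.2, 5.4, 5.6))
        ev = _bump_stack((0.0, 0.0), depths=(5.0, 5.2, 5.4, 5.6, 5.8))
        res = gamma_3d(ref, ev, CRIT33)
        assert res.pass_rate == 100.0
        _, brute_rate = _gamma3d_bruteforce(ref, ev, CRIT33, step=0.25)
        assert brute_rate == 100.0

    def test_single_plane_falls_through_to_2d(self):
        p = gaussian_bump_plane(21)
        res = gamma_3d([p], [p], CRIT33)
        assert res.pass_rate == 100.0
        assert "note" in res.meta

    @pytest.mark.parametrize("seed", range(3))
    def test_3d_superset_of_2d_on_central_plane(self, seed):
        rng = np.random.default_rng(40 + seed)
        base = _bump_stack((0.0, 0.0), n=21)
        ev_planes = []
        for p in base:
            noise = 0.02 * smooth_random_plane(rng, 21).values
            ev_planes.append(
                DosePlane(np.clip(p.values + noise, 0, None),
                          p.origin_x, p.origin_y, p.spacing, p.depth)
            )
        res3 = gamma_3d(base, ev_planes, CRIT33, search_factor=1.5)
        mid = len(base) // 2
        norm3 = float(np.stack([p.values for p in base]).max())
        res2 = gamma_2d(
            base[mid], ev_planes[mid],
            GammaCriteria(3.0, 3.0, 10.0, normalization=norm3),
            search_factor=1.5,
        )
        g3 = res3.gamma_map[mid]
        g2 = res2.gamma_map
        both = ~np.isnan(g3) & ~np.isnan(g2)
        assert np.all(g3[both] <= g2[both] + 0.02)

    def test_mismatched_lattice_rejected(self):
        a = _bump_stack((0.0, 0.0))
        b = _bump_stack((0.0, 0.0))
        b[1] = DosePlane(b[1].values, 5.0, 0.0, b[1].spacing, b[1].depth)
        with pytest.raises(InputError):
            gamma_3d(a, b, CRIT33)


class TestQaDisposition:
    def test_first_gate(self):
        d = qa_disposition(95.0, 99.0)
        assert d.status == "pass" and d.route == "2%/2mm"

    def test_second_gate(self):
        d = qa_disposition(85.0, 92.0)
        assert d.status == "pass" and d.route == "review:3%/3mm"

    def test_worked_cascade_inputs(self):
        # the documented cascade example: 80.4% at 3%/3mm rescued by a
        # 92.1% pass rate at the best 2.5D depth
        d = qa_disposition(70.0, 80.4, 92.1)
        assert d.status == "pass" and d.route == "review:2.5D"
        assert d.evidence["best25d"] == 92.1

    def test_missing_25d_forces_review(self):
        d = qa_disposition(70.0, 80.0)
        assert d.status == "review"
        assert "action_needed" in d.evidence

    def test_fail(self):
        d = qa_disposition(50.0, 60.0, 70.0)
        assert d.status == "fail"

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            qa_disposition(101.0, 50.0)

    @given(
        p22=st.floats(0, 100), p33=st.floats(0, 100),
        p25=st.one_of(st.none(), st.floats(0, 100)),
    )
    @settings(max_examples=200)
    def test_status_is_function_of_evidence(self, p22, p33, p25):
        d = qa_disposition(p22, p33, p25)
        if p22 >= 90 or p33 >= 90:
            assert d.status == "pass"
        elif p25 is None:
            assert d.status == "review"
        else:
            assert d.status == ("pass" if p25 >= 90 else "fail")
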