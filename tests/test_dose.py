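"""Beamlet engine, plan dose composition, D95 anchoring, gamma index."""

import numpy as np
import pytest

from vmatrl.dose import (BeamletBank, DoseGrid, KernelParams, NormalizationError,
                         aperture_fractions, cp_dose, d95_dose, gamma_pass_rate,
                         normalize_d95, plan_dose, precompute_beamlets)
from vmatrl.machine import ControlPoint, MachineModel, Plan, build_arc_template
from vmatrl.phantoms import Phantom, generate_phantom


def _uniform_phantom(shape=(16, 16, 16), spacing=8.0):
    masks = {"PTV": np.zeros(shape, dtype=bool)}
    masks["PTV"][6:10, 6:10, 6:10] = True
    iso = tuple((n - 1) * spacing / 2 for n in shape)
    return Phantom(grid_shape=shape, spacing=(spacing,) * 3, masks=masks,
                   isocenter=iso)


def _open_cp(machine, angle=0.0, mu=10.0, gap=4.0):
    x1 = np.full(machine.leaf_pairs, -gap / 2)
    x2 = np.full(machine.leaf_pairs, gap / 2)
    return ControlPoint(angle=angle, leaf_x1=x1, leaf_x2=x2, mu=mu)


class TestBeamletKernel:
    def test_on_axis_attenuation_ratio_is_closed_form(self):
        ph = _uniform_phantom()
        machine = MachineModel(field_half_width=6.5)
        kernel = KernelParams()
        arc = build_arc_template(90.0, gap=None)
        bank = precompute_beamlets(ph, arc, machine, kernel)
        # gantry 0: beam travels along -y; pick two on-axis voxels at depths
        # differing by exactly 2 voxels (16 mm)
        b = bank.beamlet_dose(0.0, 12, bank.n_bins // 2)
        iso_idx = 7
        d1 = b[iso_idx, 9, iso_idx]
        d2 = b[iso_idx, 7, iso_idx]
        assert d2 / d1 == pytest.approx(np.exp(-kernel.mu_mm * 16.0), rel=1e-9)

    def test_far_off_axis_dose_is_negligible(self):
        ph = _uniform_phantom()
        machine = MachineModel(field_half_width=6.5)
        bank = precompute_beamlets(ph, build_arc_template(90.0, gap=None), machine)
        b = bank.beamlet_dose(0.0, 12, bank.n_bins // 2)
        axis = b[7, 8, 7]
        corner = b[0, 8, 7]  # ~56 mm off axis, sigma = 3 mm
        assert corner < 1e-6 * axis

    def test_opposing_angles_mirror_on_symmetric_phantom(self):
        ph = _uniform_phantom()
        machine = MachineModel(field_half_width=6.5)
        bank = precompute_beamlets(ph, build_arc_template(180.0, gap=None), machine)
        cp0 = _open_cp(machine, angle=0.0)
        cp180 = _open_cp(machine, angle=180.0)
        d0 = cp_dose(cp0, bank, machine).values
        d180 = cp_dose(cp180, bank, machine).values
        # mirror through the isocenter plane perpendicular to the beam
        assert np.allclose(d180, d0[::-1, ::-1, :], atol=1e-12)

    def test_bad_kernel_parameters_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(mu_mm=-1.0)

    def test_bank_save_load_round_trip(self, tmp_path, toy_phantom, toy_arc, toy_machine):
        bank = precompute_beamlets(toy_phantom, toy_arc, toy_machine)
        bank.save(tmp_path / "bank.h5")
        back = BeamletBank.load(tmp_path / "bank.h5")
        a = bank.angles[3]
        assert np.allclose(back.attenuation[a], bank.attenuation[a])
        assert np.allclose(back.profile_z, bank.profile_z)


class TestCpDose:
    def test_closed_aperture_gives_zero_grid(self, toy_bank, toy_machine):
        cp = ControlPoint(angle=0.0, leaf_x1=np.zeros(26), leaf_x2=np.zeros(26), mu=50.0)
        assert not np.any(cp_dose(cp, toy_bank, toy_machine).values)

    def test_dose_is_linear_in_mu(self, toy_bank, toy_machine):
        cp = _open_cp(toy_machine, mu=7.0)
        cp2 = _open_cp(toy_machine, mu=14.0)
        d1 = cp_dose(cp, toy_bank, toy_machine).values
        d2 = cp_dose(cp2, toy_bank, toy_machine).values
        assert np.allclose(d2, 2.0 * d1, rtol=0, atol=0)

    def test_leaf_bisecting_a_beamlet_halves_its_dose(self, toy_bank, toy_machine):
        edges = toy_bank.u_edges
        b = toy_bank.n_bins // 2
        x1 = np.full(26, edges[b])
        cp_full = ControlPoint(0.0, x1, np.full(26, edges[b + 1]), mu=5.0)
        mid = 0.5 * (edges[b] + edges[b + 1])
        cp_half = ControlPoint(0.0, x1.copy(), np.full(26, mid), mu=5.0)
        full = cp_dose(cp_full, toy_bank, toy_machine).values
        half = cp_half_dose = cp_dose(cp_half, toy_bank, toy_machine).values
        assert np.allclose(half, 0.5 * full, atol=1e-14)

    def test_fractions_match_overlap_oracle(self, toy_bank, toy_machine, rng):
        cp = ControlPoint.from_leaf_vector(
            0.0, np.sort(rng.uniform(-5, 5, size=(2, 26)), axis=0).ravel(), mu=1.0)
        frac = aperture_fractions(cp, toy_bank)
        edges = toy_bank.u_edges
        for p in (0, 13, 25):
            for b in (0, toy_bank.n_bins // 2, toy_bank.n_bins - 1):
                lo = max(cp.leaf_x1[p], edges[b])
                hi = min(cp.leaf_x2[p], edges[b + 1])
                expect = max(hi - lo, 0.0) / (edges[b + 1] - edges[b])
                assert frac[p, b] == pytest.approx(expect)


class TestPlanDose:
    def test_blend_disabled_equals_sum_of_cp_doses(self, toy_bank, toy_machine, toy_arc):
        cps = [_open_cp(toy_machine, angle=a, mu=3.0) for a in toy_arc.angles()[:4]]
        plan = Plan(cps, "t")
        total = plan_dose(plan, toy_bank)
        manual = sum(cp_dose(cp, toy_bank, toy_machine).values for cp in cps)
        assert np.allclose(total.values, manual, rtol=1e-14)
        blended = plan_dose(plan, toy_bank, blend=True)
        assert np.allclose(blended.values, manual, rtol=1e-12)

    def test_zero_mu_plan_gives_zero_grid(self, toy_bank, toy_machine):
        plan = Plan([_open_cp(toy_machine, mu=0.0)], "z")
        assert not np.any(plan_dose(plan, toy_bank).values)

    def test_two_cp_blend_matches_weighted_sum_oracle(self):
        ph = _uniform_phantom()
        machine = MachineModel(field_half_width=6.5)
        arc = build_arc_template(90.0, gap=None)
        bank = precompute_beamlets(ph, arc, machine)  # bank at 0/90/180/270
        cp = _open_cp(machine, angle=30.0, mu=5.0)  # between 0 and 90
        plan = Plan([cp], "blend")
        blended = plan_dose(plan, bank, blend=True).values
        frac = aperture_fractions(cp, bank)
        from vmatrl.dose import _aperture_dose
        oracle = 5.0 * ((60.0 / 90.0) * _aperture_dose(frac, 0.0, bank)
                        + (30.0 / 90.0) * _aperture_dose(frac, 90.0, bank))
        assert np.allclose(blended, oracle, rtol=1e-12)

    def test_superposition_matches_brute_force_voxel_loop(self, rng):
        ph = _uniform_phantom()
        machine = MachineModel(field_half_width=6.5)
        arc = build_arc_template(90.0, gap=None)
        bank = precompute_beamlets(ph, arc, machine)
        cps = []
        for angle in arc.angles():
            leaves = np.sort(rng.uniform(-4, 4, size=(2, 26)), axis=0)
            cps.append(ControlPoint(angle, leaves[0], leaves[1],
                                    mu=float(rng.uniform(0, 5))))
        plan = Plan(cps, "brute")
        fast = plan_dose(plan, bank).values
        brute = np.zeros(ph.grid_shape)
        for cp in cps:
            frac = aperture_fractions(cp, bank)
            for p in range(26):
                for b in range(bank.n_bins):
                    if frac[p, b] > 0:
                        brute += cp.mu * frac[p, b] * bank.beamlet_dose(cp.angle, p, b)
        assert np.allclose(fast, brute, rtol=1e-10)

    def test_opening_a_leaf_pair_never_decreases_dose(self, toy_bank, toy_machine):
        cp_narrow = _open_cp(toy_machine, gap=2.0)
        cp_wide = _open_cp(toy_machine, gap=4.0)
        d_narrow = cp_dose(cp_narrow, toy_bank, toy_machine).values
        d_wide = cp_dose(cp_wide, toy_bank, toy_machine).values
        assert np.all(d_wide >= d_narrow - 1e-15)


class TestNormalizeD95:
    def test_anchored_grid_has_unit_d95(self, toy_phantom, toy_bank, toy_machine):
        plan = Plan([_open_cp(toy_machine, angle=a, mu=5.0)
                     for a in toy_bank.angles[:6]], "n")
        anchored, _ = normalize_d95(plan_dose(plan, toy_bank), toy_phantom.masks["PTV"])
        assert d95_dose(anchored.values, toy_phantom.masks["PTV"]) == pytest.approx(1.0)

    def test_global_rescale_leaves_anchored_dose_invariant(self, toy_phantom, toy_bank,
                                                           toy_machine):
        plan = Plan([_open_cp(toy_machine, mu=5.0)], "s")
        raw = plan_dose(plan, toy_bank)
        a1, _ = normalize_d95(raw, toy_phantom.masks["PTV"])
        scaled = DoseGrid(raw.values * 7.3, raw.spacing, "raw")
        a2, _ = normalize_d95(scaled, toy_phantom.masks["PTV"])
        assert np.allclose(a1.values, a2.values, rtol=1e-12)

    def test_twenty_voxel_oracle(self, rng):
        # D95 of 20 sorted voxel doses is the 19th largest value
        doses = rng.uniform(0.5, 2.0, size=20)
        mask = np.ones(20, dtype=bool)
        expect = np.sort(doses)[::-1][18]
        assert d95_dose(doses, mask) == pytest.approx(expect)

    def test_zero_ptv_dose_raises(self, toy_phantom):
        zero = DoseGrid(np.zeros(toy_phantom.grid_shape), toy_phantom.spacing, "raw")
        with pytest.raises(NormalizationError):
            normalize_d95(zero, toy_phantom.masks["PTV"])


def _brute_force_gamma(ev, ref, spacing, dose_crit, dist_crit, threshold, radius):
    ref_max = ref.max()
    dd = dose_crit / 100 * ref_max
    passed = total = 0
    shape = ref.shape
    for idx in np.ndindex(shape):
        if ref[idx] < threshold / 100 * ref_max:
            continue
        total += 1
        best = np.inf
        for off in np.ndindex((5, 5, 5)):
            o = np.array(off) - 2
            r = np.linalg.norm(o * spacing)
            if r > radius:
                continue
            j = np.array(idx) + o
            if np.any(j < 0) or np.any(j >= shape):
                continue
            g = ((ev[tuple(j)] - ref[idx]) / dd) ** 2 + (r / dist_crit) ** 2
            best = min(best, g)
        passed += best <= 1.0 + 1e-12
    return 100.0 * passed / total


class TestGamma:
    def _grids(self, values, spacing=5.0):
        return DoseGrid(values, (spacing,) * 3, "raw")

    def test_self_comparison_is_100(self, rng):
        v = rng.uniform(0.1, 2.0, size=(6, 6, 6))
        assert gamma_pass_rate(self._grids(v), self._grids(v)) == 100.0

    def test_2p9_percent_uniform_scaling_passes_3_2(self, rng):
        v = rng.uniform(0.5, 1.0, size=(6, 6, 6))
        assert gamma_pass_rate(self._grids(v), self._grids(v * 1.029)) == 100.0

    def test_6_percent_scaling_of_flat_dose_fails_everywhere(self):
        flat = np.full((6, 6, 6), 1.0)
        rate = gamma_pass_rate(self._grids(flat * 1.06), self._grids(flat))
        assert rate == 0.0

    def test_matches_brute_force_oracle(self, rng):
        ref = rng.uniform(0.0, 1.0, size=(5, 5, 5))
        ev = ref + rng.normal(scale=0.04, size=ref.shape)
        got = gamma_pass_rate(self._grids(ev), self._grids(ref))
        expect = _brute_force_gamma(ev, ref, np.array([5.0] * 3), 3.0, 2.0, 10.0, 6.0)
        assert got == pytest.approx(expect)

    def test_geometry_mismatch_rejected(self, rng):
        a = self._grids(rng.uniform(size=(5, 5, 5)))
        b = DoseGrid(rng.uniform(size=(5, 5, 5)), (4.0,) * 3, "raw")
        with pytest.raises(ValueError):
            gamma_pass_rate(a, b)
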