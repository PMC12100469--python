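"""Dosimetric evaluation battery: gamma, range maps/ARD, MAE, DSC, DVH, RDE."""

import numpy as np
import pytest

from pb2mc.dosemetrics import (DVHCurve, EvalConfig, EvalReport, ard, dvh,
                               dvh_metric, evaluate_beam, evaluate_plan,
                               gamma_3d, isodose_dsc, mae, passing_rate,
                               range_map, rde, RangeMap)
from pb2mc.grids import BeamGeometry, VolumeGrid

from _oracles import brute_force_gamma


def random_dose_pair(rng, shape=(12, 12, 12), noise=0.05):
    ref = rng.random(shape) * 2.0
    ev = np.clip(ref + rng.normal(0, noise, shape), 0.0, None)
    return (VolumeGrid(ref, (2.0, 2.0, 2.0)), VolumeGrid(ev, (2.0, 2.0, 2.0)))


class TestGamma:
    def test_identity_gives_zero_gamma(self, rng):
        ref, _ = random_dose_pair(rng)
        res = gamma_3d(ref, ref, 3.0, 3.0, 10.0)
        assert np.nanmax(res.gamma_values) == 0.0
        assert passing_rate(res) == 100.0

    def test_global_scaling_bound(self, rng):
        """evaluated = 1.03 x reference passes 3%/anything at 100% under
        global normalisation."""
        ref, _ = random_dose_pair(rng)
        scaled = ref.copy_with(ref.values * 1.03)
        res = gamma_3d(ref, scaled, 3.0, 3.0, 10.0)
        assert np.nanmax(res.gamma_values) <= 1.0 + 1e-12
        assert passing_rate(res) == 100.0

    def test_agrees_with_brute_force_oracle(self, rng):
        worst = 0.0
        for _ in range(20):
            ref, ev = random_dose_pair(rng)
            res = gamma_3d(ref, ev, 3.0, 3.0, 10.0)
            oracle = brute_force_gamma(ref.values, ev.values, 3.0, 3.0, 10.0,
                                       ref.spacing)
            m = res.evaluated_mask
            worst = max(worst, np.nanmax(np.abs(res.gamma_values[m] - oracle[m])))
        assert worst <= 0.02

    def test_passing_rate_counts_boundary(self):
        from pb2mc.dosemetrics import GammaResult

        g = np.full((1, 1, 4), np.nan)
        g[0, 0] = [0.5, 1.0, 1.5, 2.0]
        mask = np.ones((1, 1, 4), bool)
        r = GammaResult(g, (3, 3), 1.0, 10.0, mask)
        assert passing_rate(r) == 50.0

    def test_excluded_voxels_not_counted(self):
        from pb2mc.dosemetrics import GammaResult

        g = np.full((1, 1, 4), np.nan)
        g[0, 0, :2] = [0.5, 2.0]
        mask = np.zeros((1, 1, 4), bool)
        mask[0, 0, :2] = True
        r = GammaResult(g, (3, 3), 1.0, 10.0, mask)
        assert passing_rate(r) == 50.0

    def test_monotone_in_criteria(self, rng):
        ref, ev = random_dose_pair(rng, noise=0.08)
        rates = [
            passing_rate(gamma_3d(ref, ev, pct, mm, 10.0))
            for pct, mm in ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0))
        ]
        assert rates[0] <= rates[1] <= rates[2]

    def test_threshold_applies_to_reference(self, rng):
        ref, ev = random_dose_pair(rng)
        res = gamma_3d(ref, ev, 3.0, 3.0, 40.0)
        thr = 0.40 * ref.values.max()
        assert np.array_equal(res.evaluated_mask, ref.values >= thr)

    def test_lattice_mismatch_rejected(self, rng):
        ref, _ = random_dose_pair(rng)
        other = VolumeGrid(ref.values, (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="lattice"):
            gamma_3d(ref, other, 3.0, 3.0, 10.0)

    def test_empty_mask_rejected(self, rng):
        ref, ev = random_dose_pair(rng)
        with pytest.raises(ValueError, match="mask"):
            gamma_3d(ref, ev, 3.0, 3.0, 10.0, np.zeros(ref.shape, bool))


class TestRangeMap:
    def profile_grid(self, profile):
        vals = np.tile(np.asarray(profile, float), (3, 3, 1))
        return VolumeGrid(vals, (2.0, 2.0, 2.0))

    def test_exact_crossing_at_voxel_center(self):
        # rises above, crosses the threshold exactly at a voxel centre
        prof = [0.0, 1.2, 1.2, 0.9, 0.3, 0.0]
        rm = range_map(self.profile_grid(prof), 0.9, 1.0)
        assert rm.ranges[1, 1] == pytest.approx(2.0 * 3, abs=1e-9)

    def test_interpolated_crossing(self):
        prof = [0.0, 1.2, 1.2, 1.0, 0.5, 0.0]
        # crossing of 0.9 between k=3 (1.0) and k=4 (0.5): frac = 0.2
        rm = range_map(self.profile_grid(prof), 0.9, 1.0)
        assert rm.ranges[1, 1] == pytest.approx(2.0 * 3.2, abs=1e-9)

    def test_distal_most_crossing_wins(self):
        prof = [0.0, 1.2, 0.3, 1.2, 1.0, 0.5, 0.0]
        rm = range_map(self.profile_grid(prof), 0.9, 1.0)
        # the last downward crossing is after k=4, not after k=1
        assert rm.ranges[1, 1] > 2.0 * 4

    def test_no_crossing_is_nan(self):
        prof = [0.0, 0.2, 0.3, 0.2, 0.0, 0.0]
        rm = range_map(self.profile_grid(prof), 0.9, 1.0)
        assert np.isnan(rm.ranges[1, 1])

    def test_translation_shifts_ranges(self, rng):
        base = np.zeros((4, 4, 30))
        base[:, :, 5:18] = 1.2
        base[:, :, 18] = 0.6
        g = VolumeGrid(base, (2.0, 2.0, 2.0))
        shifted = VolumeGrid(np.roll(base, 3, axis=2), (2.0, 2.0, 2.0))
        r0 = range_map(g, 0.9, 1.0)
        r1 = range_map(shifted, 0.9, 1.0)
        assert np.allclose(r1.ranges - r0.ranges, 3 * 2.0, atol=1e-6)

    def test_sobp_range_matches_analytic_model(self):
        """Homogeneous water: the axis-ray R90 equals the depth where the
        SOBP model crosses 0.9 x prescription, within half a voxel."""
        from pb2mc.phantom import BeamSimSpec, build_sobp, simulate_mc_like

        shape, sp = (24, 24, 64), (2.0, 2.0, 2.0)
        ct = VolumeGrid(np.zeros(shape), sp)
        body = VolumeGrid(np.ones(shape, np.uint8), sp)
        ctvv = np.zeros(shape, np.uint8)
        ctvv[8:16, 8:16, 30:45] = 1
        ctv = VolumeGrid(ctvv, sp)
        beam = BeamSimSpec(gantry_deg=270, couch_deg=0,
                           isocenter=(23.0, 23.0, 74.0), nominal_range=90.0,
                           modulation=35.0, field_halfwidth_si=20.0,
                           field_halfwidth_ap=20.0, entrance_sigma=3.0,
                           sigma_growth=0.0)
        dd = build_sobp(beam.nominal_range, beam.modulation)
        mc = simulate_mc_like(ct, beam, dd, body, ctv)
        rm = range_map(mc, 0.9, beam.prescribed_dose)
        # analytic: rescale the model the same way (CTV median = Rx) and
        # find its distal 0.9 x Rx crossing on a fine grid
        fine = np.arange(0.0, 130.0, 0.01)
        scale = beam.prescribed_dose / np.median(
            dd((np.arange(30, 45) + 0.5 - 0) * 2.0 - 1.0)
        )
        curve = dd(fine) * scale
        crossing = fine[np.max(np.nonzero(curve >= 0.9 * beam.prescribed_dose))]
        axis_range = rm.ranges[11, 11] + 1.0  # midpoint-rule WED offset
        assert abs(axis_range - crossing) < 1.0  # half a voxel


class TestARD:
    def two_maps(self, ref_vals, eval_vals):
        mk = lambda v: RangeMap(np.asarray(v, float), 0.9, (2.0, 2.0, 2.0))
        return mk(ref_vals), mk(eval_vals)

    def test_identity_is_zero(self):
        r, e = self.two_maps([[100.0, 120.0]], [[100.0, 120.0]])
        assert ard(r, e) == 0.0

    def test_uniform_inflation(self):
        ref = np.full((5, 5), 80.0)
        r, e = self.two_maps(ref, 1.02 * ref)
        assert ard(r, e) == pytest.approx(-2.0, abs=1e-12)

    def test_hand_computed_two_rays(self):
        r, e = self.two_maps([[100.0, 200.0]], [[99.0, 202.0]])
        # 100 * 0.5 * (1/100 - 2/200) = 0
        assert ard(r, e) == pytest.approx(0.0, abs=1e-12)

    def test_nan_rays_dropped(self):
        r, e = self.two_maps([[100.0, np.nan]], [[102.0, 50.0]])
        assert ard(r, e) == pytest.approx(-2.0, abs=1e-12)

    def test_no_joint_rays_rejected(self):
        r, e = self.two_maps([[np.nan]], [[50.0]])
        with pytest.raises(ValueError, match="finite"):
            ard(r, e)


class TestMAE:
    def test_identity_and_offset(self, rng):
        ref, _ = random_dose_pair(rng)
        mask = np.ones(ref.shape, bool)
        assert mae(ref, ref, mask, 0.1, 2.0) == 0.0
        off = ref.copy_with(ref.values + 0.5)
        assert mae(ref, off, mask, 0.1, 2.0) == pytest.approx(0.5, abs=1e-12)

    def test_arithmetic_mean(self):
        ref = VolumeGrid(np.array([[[1.0, 1.0, 1.0]]]), (1, 1, 1))
        ev = VolumeGrid(np.array([[[2.0, 3.0, 7.0]]]), (1, 1, 1))
        assert mae(ref, ev, np.ones((1, 1, 3), bool), 0.1, 1.0) == 3.0

    def test_threshold_excludes_low_reference(self):
        ref = VolumeGrid(np.array([[[0.05, 1.0]]]), (1, 1, 1))
        ev = VolumeGrid(np.array([[[5.0, 1.5]]]), (1, 1, 1))
        assert mae(ref, ev, np.ones((1, 1, 2), bool), 0.1, 1.0) == 0.5

    def test_symmetry(self, rng):
        ref, ev = random_dose_pair(rng)
        mask = np.ones(ref.shape, bool)
        assert mae(ref, ev, mask, 0.0, 1.0) == pytest.approx(
            np.mean(np.abs(ref.values - ev.values)))

    def test_empty_set_rejected(self):
        ref = VolumeGrid(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            mae(ref, ref, np.zeros((2, 2, 2), bool), 0.1, 1.0)


class TestDSC:
    def test_identical_doses(self, rng):
        ref, _ = random_dose_pair(rng)
        assert isodose_dsc(ref, ref, 10.0, 50.0, 2.0) == 1.0

    def test_disjoint_sets(self):
        a = np.zeros((2, 2, 2))
        a[0] = 0.4  # 20% band member for prescription 2.0
        b = np.zeros((2, 2, 2))
        b[1] = 0.4
        ga, gb = VolumeGrid(a, (1, 1, 1)), VolumeGrid(b, (1, 1, 1))
        assert isodose_dsc(ga, gb, 10.0, 30.0, 2.0) == 0.0

    def test_counting_definition(self):
        # |A| = 4, |B| = 2, |A & B| = 2 -> 2*2/6
        a = np.zeros((1, 1, 8))
        a[0, 0, :4] = 0.5
        b = np.zeros((1, 1, 8))
        b[0, 0, 2:4] = 0.5
        ga, gb = VolumeGrid(a, (1, 1, 1)), VolumeGrid(b, (1, 1, 1))
        assert isodose_dsc(ga, gb, 10.0, 30.0, 2.0) == pytest.approx(4 / 6)

    def test_symmetric(self, rng):
        ref, ev = random_dose_pair(rng)
        assert isodose_dsc(ref, ev, 10.0, 70.0, 2.0) == pytest.approx(
            isodose_dsc(ev, ref, 10.0, 70.0, 2.0))

    def test_upper_bound_exclusive(self):
        # a voxel at exactly 30% of prescription is NOT in [10%, 30%)
        v = np.zeros((1, 1, 2))
        v[0, 0, 0] = 0.6  # 30% of prescription 2.0
        v[0, 0, 1] = 0.4  # 20%
        g = VolumeGrid(v, (1, 1, 1))
        other = VolumeGrid(np.full((1, 1, 2), 0.4), (1, 1, 1))
        # band [10, 30): g contributes only the 20% voxel, other both
        assert isodose_dsc(g, other, 10.0, 30.0, 2.0) == pytest.approx(2 / 3)
        # both sets empty in a band nothing occupies
        with pytest.raises(ValueError, match="empty"):
            isodose_dsc(g, g, 40.0, 50.0, 2.0)


class TestDVH:
    def test_uniform_dose(self):
        g = VolumeGrid(np.full((4, 4, 4), 1.8), (1, 1, 1))
        curve = dvh(g, np.ones((4, 4, 4), bool))
        for x in (98, 95, 50, 2):
            assert dvh_metric(curve, x) == pytest.approx(1.8)
        assert curve.volume_pct[0] == 100.0
        assert np.all(np.diff(curve.volume_pct) <= 1e-12)

    def test_sorted_percentile_oracle(self):
        vals = np.arange(1.0, 101.0).reshape(4, 5, 5)
        g = VolumeGrid(vals, (1, 1, 1))
        curve = dvh(g, np.ones((4, 5, 5), bool))
        assert dvh_metric(curve, 50.0) == pytest.approx(50.5)
        for x in (98, 95, 50, 2):
            assert dvh_metric(curve, x) == pytest.approx(
                np.percentile(vals, 100 - x))

    def test_metric_nonincreasing_in_x(self, rng):
        g = VolumeGrid(rng.random((6, 6, 6)), (1, 1, 1))
        curve = dvh(g, np.ones((6, 6, 6), bool))
        ds = [dvh_metric(curve, x) for x in (2, 50, 95, 98)]
        assert all(a >= b for a, b in zip(ds, ds[1:]))

    def test_empty_mask_rejected(self):
        g = VolumeGrid(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            dvh(g, np.zeros((2, 2, 2), bool))


class TestRDE:
    def test_examples(self):
        assert rde(50.0, 50.0) == 0.0
        assert rde(1.037 * 60.0, 60.0) == pytest.approx(3.7)
        assert rde(51.0, 50.0) == pytest.approx(2.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rde(1.0, 0.0)


class TestReports:
    def scene(self, rng):
        shape, sp = (16, 24, 24), (4.0, 4.0, 4.0)
        ax = [np.arange(n) * 4.0 for n in shape]
        mesh = np.meshgrid(*ax, indexing="ij")
        iso = (30.0, 46.0, 46.0)
        r2 = sum((mesh[a] - iso[a]) ** 2 for a in range(3))
        mc = VolumeGrid(2.0 * np.exp(-r2 / (2 * 18.0**2)), sp)
        body = VolumeGrid((r2 <= 40.0**2).astype(np.uint8), sp)
        ctv = VolumeGrid((r2 <= 10.0**2).astype(np.uint8), sp)
        beam = BeamGeometry(270.0, 0.0, iso, 2.0)
        return mc, body, ctv, beam

    def test_identity_cascade_beam(self, rng):
        mc, body, ctv, beam = self.scene(rng)
        rep = evaluate_beam(mc, mc, mc, beam, body, subject_id="b0")
        assert rep.metrics["gamma_3_3_dl"] == 100.0
        assert rep.metrics["ard_r90_dl"] == 0.0
        assert rep.metrics["ard_r50_dl"] == 0.0
        assert rep.metrics["mae_dl"] == 0.0

    def test_identity_cascade_plan(self, rng):
        mc, body, ctv, beam = self.scene(rng)
        rep = evaluate_plan(mc, mc, mc, body, ctv, 2.0, subject_id="p0")
        for crit in ("1_1", "2_2", "3_3"):
            assert rep.metrics[f"gamma_{crit}_dl"] == 100.0
        assert rep.metrics["mae_dl"] == 0.0
        for lo, hi in ((10, 30), (10, 50), (10, 70), (10, 90)):
            assert rep.metrics[f"dsc_{lo}_{hi}_dl"] == 1.0
        for x in (98, 95, 50, 2):
            assert rep.metrics[f"rde_d{x}_dl"] == 0.0

    def test_report_json_round_trip(self, rng, tmp_path):
        mc, body, ctv, beam = self.scene(rng)
        rep = evaluate_beam(mc, mc, mc, beam, body, subject_id="b1")
        path = tmp_path / "rep.json"
        rep.to_json(path)
        back = EvalReport.from_json(path)
        assert back.kind == rep.kind
        assert back.subject_id == rep.subject_id
        assert back.metrics == rep.metrics
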