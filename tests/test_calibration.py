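"""Fixed-vial calibration: planning, back-calculation, correction, fitting,
LED selection, temperature calibration, store management, media equivalence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from turbistat import protocols
from turbistat import virtualrig as vr
from turbistat.calibration import (
    CalibrationDataset,
    CalibrationPoint,
    CalibrationStore,
    backcalculate_stock,
    check_media_equivalence,
    commanded_temperature,
    correct_calibration,
    default_target_ods,
    fit_curve,
    fit_temp_map,
    media_equivalence_report,
    plan_inoculation,
    plan_temp_calibration,
    select_led_power,
)


class TestInoculationPlanning:
    def test_pbs_only_plan(self):
        plan = plan_inoculation([0.0], 25.0, 20.0)
        assert len(plan.steps) == 1
        assert plan.steps[0].added_volume_ml == 0.0
        assert plan.steps[0].nominal_od == 0.0

    def test_volume_accounts_for_added_stock(self):
        # 20 * v / (25 + v) = 0.2  =>  v = 0.2*25/19.8
        plan = plan_inoculation([0.2], 25.0, 20.0)
        v = plan.steps[-1].cumulative_stock_volume_ml
        assert v == pytest.approx(0.2 * 25 / 19.8, rel=1e-12)
        assert v == pytest.approx(0.2525, abs=5e-4)
        assert plan.steps[-1].nominal_od == pytest.approx(
            20.0 * v / (25.0 + v), rel=1e-12
        )

    def test_repeated_target_adds_nothing(self):
        plan = plan_inoculation([0.2, 0.2], 25.0, 20.0)
        assert plan.steps[-1].added_volume_ml == pytest.approx(0.0, abs=1e-15)

    def test_decreasing_targets_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            plan_inoculation([0.3, 0.2], 25.0, 20.0)

    def test_dilute_stock_rejected(self):
        with pytest.raises(ValueError, match="too dilute"):
            plan_inoculation([0.8], 25.0, 10.0)

    def test_cumulative_quantities_strictly_increase(self):
        plan = plan_inoculation(default_target_ods(), 25.0, 20.0)
        fr = plan.cumulative_fractions
        assert np.all(np.diff(fr[1:]) > 0) and fr[0] == 0.0
        # fraction identity: cumulative fraction equals nominal od / stock od
        assert fr == pytest.approx(plan.nominal_ods / 20.0, rel=1e-12)


class TestStockBackCalculation:
    def test_backcalculated_stock_from_endpoint_od(self):
        # final fraction t/S = 0.6/20 = 0.03 exactly
        plan = plan_inoculation([0.3, 0.6], 25.0, 20.0)
        assert plan.final_fraction == pytest.approx(0.03, rel=1e-12)
        stock, corrected = backcalculate_stock(plan, [0.618])
        assert stock == pytest.approx(20.6, rel=1e-12)
        assert corrected == pytest.approx(plan.nominal_ods * 1.03, rel=1e-12)

    def test_accurate_stock_leaves_ods_unchanged(self):
        plan = plan_inoculation([0.2, 0.4], 25.0, 20.0)
        _, corrected = backcalculate_stock(plan, [plan.nominal_ods[-1]])
        assert corrected == pytest.approx(plan.nominal_ods, rel=1e-12)

    def test_pbs_point_stays_zero(self):
        plan = plan_inoculation([0.2, 0.4], 25.0, 20.0)
        _, corrected = backcalculate_stock(plan, [0.5])
        assert corrected[0] == 0.0

    def test_multiple_endpoint_measurements_averaged(self):
        plan = plan_inoculation([0.6], 25.0, 20.0)
        stock, _ = backcalculate_stock(plan, [0.59, 0.61])
        assert stock == pytest.approx(0.60 / 0.03, rel=1e-12)

    def test_empty_measurements_rejected(self):
        plan = plan_inoculation([0.2], 25.0, 20.0)
        with pytest.raises(ValueError, match="no endpoint"):
            backcalculate_stock(plan, [])

    def test_pbs_only_plan_cannot_backcalculate(self):
        plan = plan_inoculation([0.0], 25.0, 20.0)
        with pytest.raises(ValueError, match="zero final"):
            backcalculate_stock(plan, [0.5])

    @given(k=st.floats(0.5, 2.0))
    def test_scale_consistency(self, k):
        """Scaling every endpoint OD by k scales the stock and all points by k."""
        plan = plan_inoculation([0.2, 0.5], 25.0, 20.0)
        stock1, corr1 = backcalculate_stock(plan, [0.5, 0.52])
        stock2, corr2 = backcalculate_stock(plan, [0.5 * k, 0.52 * k])
        assert stock2 == pytest.approx(k * stock1, rel=1e-12)
        assert corr2 == pytest.approx(k * corr1, rel=1e-12)


def _dataset(raws, ods, sds=None):
    sds = sds if sds is not None else [10.0] * len(raws)
    points = [
        CalibrationPoint(raw_mean=r, raw_sd=s, nominal_od=o)
        for r, s, o in zip(raws, sds, ods)
    ]
    return CalibrationDataset("S0", "V0", 2, points)


class TestCorrection:
    def test_identity_correction_preserves_points(self):
        ds = _dataset([41000, 39000, 36000], [0.0, 0.2, 0.5])
        out = correct_calibration(ds, [0.0, 0.2, 0.5])
        assert out.corrected and out.monotone_ok
        assert [p.corrected_od for p in out.points] == [0.0, 0.2, 0.5]
        assert [p.raw_mean for p in out.points] == [41000, 39000, 36000]

    def test_rescaled_ods_leave_raws_untouched(self):
        ds = _dataset([41000, 39000, 36000], [0.0, 0.2, 0.5])
        out = correct_calibration(ds, np.array([0.0, 0.2, 0.5]) * 1.03)
        assert out.points[2].corrected_od == pytest.approx(0.515)
        assert out.raw_means == pytest.approx(ds.raw_means)

    def test_length_mismatch_rejected(self):
        ds = _dataset([41000, 39000], [0.0, 0.2])
        with pytest.raises(ValueError, match="corrected ODs"):
            correct_calibration(ds, [0.0, 0.2, 0.5])

    def test_shuffled_input_without_pbs_first_rejected(self):
        with pytest.raises(ValueError, match="PBS"):
            _dataset([39000, 41000], [0.2, 0.0])
        ds = _dataset([41000, 39000], [0.0, 0.2])
        with pytest.raises(ValueError, match="PBS"):
            correct_calibration(ds, [0.2, 0.0])

    def test_non_monotone_beyond_noise_flagged(self):
        ds = _dataset([41000, 39000, 40500, 36000], [0.0, 0.2, 0.3, 0.5])
        with pytest.warns(UserWarning, match="not monotone"):
            out = correct_calibration(ds, [0.0, 0.2, 0.3, 0.5])
        assert not out.monotone_ok


class TestCurveFit:
    def test_noise_free_round_trip(self, optics, vial, exact_curve):
        """The fitted map composed with the true optics is the identity."""
        grid = np.linspace(0.0, 0.8, 161)
        errs = [
            abs(exact_curve.od_from_raw(float(optics.g(od)) + vial.glass_offset) - od)
            for od in grid
        ]
        assert max(errs) < 0.005

    def test_fit_is_deterministic(self, optics, vial):
        a = protocols.calibrate_position(optics, vial, noise=False, rng=0)
        b = protocols.calibrate_position(optics, vial, noise=False, rng=0)
        assert a.params == b.params

    def test_anchor_maps_to_zero_od(self, exact_curve):
        assert abs(exact_curve.od_from_raw(exact_curve.raw_0_cal)) < 0.005

    def test_too_few_points_rejected(self):
        ds = _dataset([41000, 40000, 39000], [0.0, 0.1, 0.2])
        with pytest.raises(ValueError, match=">= 5"):
            fit_curve(ds)

    def test_noisy_fit_median_error(self, optics):
        """Median |f(raw_mean_i) - corrected_od_i| stays under 0.01 OD at 8
        points spanning the working range, across 100 noisy calibrations."""
        targets = default_target_ods(8, 0.6)
        medians = []
        for child in np.random.SeedSequence(9).spawn(100):
            rng = np.random.default_rng(child)
            vial = vr.TrueVial("V", glass_offset=float(rng.normal(0, 250)))
            plan = plan_inoculation(targets, vial.volume_ml, 20.0)
            ds, final = vr.simulate_calibration_run(optics, vial, plan, rng=rng)
            _, corrected = backcalculate_stock(plan, [final])
            ds = correct_calibration(ds, corrected)
            curve = fit_curve(ds)
            errs = [
                abs(curve.od_from_raw(p.raw_mean) - p.corrected_od)
                for p in ds.points
            ]
            medians.append(float(np.median(errs)))
        assert np.median(medians) < 0.01
        assert np.mean(medians) < 0.01

    def test_increasing_raw_direction_also_fits(self):
        """Downstream code assumes monotonicity only, not a sign convention."""
        od = np.array(default_target_ods(8, 0.8))
        raw = 45000.0 + (-12000.0) / (1 + np.exp((od - 0.35) / 0.18))  # increasing
        ds = _dataset(list(raw), list(od), sds=[0.0] * len(od))
        ds = correct_calibration(ds, od)
        curve = fit_curve(ds)
        for o, r in zip(od, raw):
            assert curve.od_from_raw(float(r)) == pytest.approx(o, abs=1e-6)


@pytest.fixture(scope="module")
def curves():
    out = {}
    for power in (1, 2, 3):
        optics = vr.make_optics("S0", power)
        vial = vr.TrueVial("V0", glass_offset=50.0)
        out[power] = protocols.calibrate_position(optics, vial, noise=False, rng=0)
    return out


class TestLedSelection:
    def test_steepest_construction_selected(self, curves):
        assert select_led_power(curves) == 3

    def test_single_candidate_returned(self, curves):
        assert select_led_power({2: curves[2]}) == 2

    def test_tie_breaks_to_lower_power(self, curves):
        assert select_led_power({1: curves[1], 5: curves[1]}) == 1

    def test_agrees_with_dense_grid_oracle(self, curves):
        """Brute-force: numerically evaluate |d raw/d OD| on a dense grid."""
        grid = np.linspace(0.2, 0.5, 2001)
        worst = {}
        for power, curve in curves.items():
            raws = np.array([curve.raw_from_od(float(o)) for o in grid])
            worst[power] = np.abs(np.gradient(raws, grid)).min()
        oracle = max(sorted(worst), key=lambda p: (worst[p], -p))
        assert select_led_power(curves) == oracle

    def test_window_outside_every_curve_rejected(self, curves):
        with pytest.raises(ValueError, match="window"):
            select_led_power(curves, od_window=(0.9, 1.1))


class TestTemperatureCalibration:
    @pytest.mark.parametrize("rt", [18.0, 22.0, 25.5])
    def test_setpoints_are_rt_plus_6_plus_12(self, rt):
        plan = plan_temp_calibration(rt)
        assert plan.setpoints_c == (rt, rt + 6.0, rt + 12.0)

    def test_exact_line_recovered(self):
        surface = [22.0, 28.0, 34.0]
        pairs = [(s, 1.05 * s - 1.0) for s in surface]
        slope, intercept = fit_temp_map(pairs)
        assert slope == pytest.approx(1.05, abs=1e-12)
        assert intercept == pytest.approx(-1.0, abs=1e-9)

    def test_offset_shifts_commanded_target(self):
        assert commanded_temperature(32.0, 0.15) == pytest.approx(32.15)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="three"):
            fit_temp_map([(22, 22), (28, 28)])

    def test_non_increasing_references_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            fit_temp_map([(22, 22), (28, 28), (34, 27)])


class TestCalibrationStore:
    def test_add_get_delete_cycle(self, exact_curve, tmp_path):
        store = CalibrationStore(tmp_path / "store.json")
        cid = store.add(exact_curve, "S0:V0:test")
        assert store.get(cid).params == exact_curve.params
        store.delete(cid)
        assert cid not in store.ids()

    def test_persistence_across_instances(self, exact_curve, tmp_path):
        path = tmp_path / "store.json"
        CalibrationStore(path).add(exact_curve, "keep")
        assert CalibrationStore(path).get("keep").raw_0_cal == exact_curve.raw_0_cal

    def test_unknown_id_rejected(self, tmp_path):
        with pytest.raises(KeyError, match="unknown"):
            CalibrationStore(tmp_path / "s.json").delete("nope")

    def test_in_use_calibration_protected(self, exact_curve, tmp_path):
        store = CalibrationStore(tmp_path / "s.json")
        cid = store.add(exact_curve)
        with pytest.raises(ValueError, match="active"):
            store.delete(cid, in_use=[cid])
        assert cid in store.ids()


class TestMediaEquivalence:
    def test_reference_differences_against_water(self):
        report = media_equivalence_report()
        assert report.loc["water", "diff_raw"] == 0.0
        assert report.loc["PBS", "diff_raw"] == -180.0
        assert report.loc["YE4S", "diff_raw"] == 162.0

    def test_custom_scans_and_missing_reference(self):
        scans = {"water": {"raw_mean": 100.0, "raw_sd": 1.0}, "X": {"raw_mean": 90.0, "raw_sd": 1.0}}
        assert media_equivalence_report(scans).loc["X", "diff_raw"] == -10.0
        with pytest.raises(KeyError):
            media_equivalence_report(scans, reference="PBS")

    def test_equivalence_threshold(self):
        assert check_media_equivalence(41115.0, 41200.0, noise_sd=50.0)
        assert not check_media_equivalence(41115.0, 41400.0, noise_sd=50.0)

    def test_simulated_pbs_and_medium_blanks_agree_within_noise(self, optics, vial):
        """On the rig PBS and medium scatter identically up to read noise, so
        medians of repeated blanks agree within 3x the noise SD."""
        rng = np.random.default_rng(5)
        pbs = np.median([vr.measure_raw(optics, vial, None, rng) for _ in range(5)])
        medium = np.median([vr.measure_raw(optics, vial, None, rng) for _ in range(5)])
        assert check_media_equivalence(pbs, medium, optics.noise_sd)


class TestDatasetIO:
    def test_tsv_round_trip(self, optics, vial, tmp_path):
        plan = plan_inoculation(default_target_ods(6, 0.5), 25.0, 20.0)
        ds, final = vr.simulate_calibration_run(optics, vial, plan, rng=3)
        _, corrected = backcalculate_stock(plan, [final])
        ds = correct_calibration(ds, corrected)
        path = ds.to_tsv(tmp_path / "cal.tsv")
        back = CalibrationDataset.from_tsv(path)
        assert back.corrected
        assert back.raw_0_cal == ds.raw_0_cal
        assert back.ods == pytest.approx(ds.ods)
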