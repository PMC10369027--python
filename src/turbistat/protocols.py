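"""End-to-end study routines wiring the full measurement chain together.

Each routine runs the complete path a real assay would take — fixed-vial
calibration, stock back-calculation, curve fit, medium blank, delta-raw OD,
turbidostat control — on the virtual rig, and reports the quantities a user
would judge the rig by (recovered doubling times, band occupancy, swap-cure
errors).  They are the package's reference experiments: the examples print
them and the validation suite asserts on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import virtualrig as vr
from .calibration import (
    CalibrationCurve,
    backcalculate_stock,
    correct_calibration,
    default_target_ods,
    fit_curve,
    plan_inoculation,
)
from .controller import ControllerConfig, ExperimentLog, VirtualTurbidostat
from .monitor import Bottle, BottleLedger
from .od_engine import BlankRecord, compute_od, record_blank
from .vial_service import ReplacementSession, reset_blank

__all__ = [
    "calibrate_position",
    "measure_blank",
    "doubling_time_recovery_study",
    "SoakResult",
    "soak_test",
    "vial_swap_study",
]

#: OD of the concentrated calibration stock (nominal). 25x the top
#: calibration OD, so all inoculations together stay under ~4% of the vial
#: volume and the volume correction in the plan stays small.
DEFAULT_STOCK_OD = 20.0


def calibrate_position(
    optics: vr.TrueOptics,
    vial: vr.TrueVial,
    *,
    stock_od_actual: float | None = None,
    reads_per_point: int = 5,
    noise: bool = True,
    spectro_sd: float = 0.0,
    n_points: int = 10,
    max_od: float = 0.8,
    rng=None,
) -> CalibrationCurve:
    """Full fixed-vial calibration of one sleeve position on the virtual rig.

    PBS anchor, geometric inoculation ladder to ``max_od``, endpoint
    spectrophotometer read, stock back-calculation, dataset correction and
    monotone curve fit.  ``stock_od_actual`` emulates a mis-measured stock;
    the back-calculation removes exactly that error.
    """
    plan = plan_inoculation(
        default_target_ods(n_points, max_od), vial.volume_ml, DEFAULT_STOCK_OD
    )
    dataset, measured_final = vr.simulate_calibration_run(
        optics,
        vial,
        plan,
        stock_od_actual=stock_od_actual,
        reads_per_point=reads_per_point,
        spectro_sd=spectro_sd,
        noise=noise,
        rng=rng,
    )
    _, corrected = backcalculate_stock(plan, [measured_final])
    dataset = correct_calibration(dataset, corrected)
    return fit_curve(dataset)


def measure_blank(
    optics: vr.TrueOptics,
    vial: vr.TrueVial,
    *,
    n_reads: int = 5,
    noise: bool = True,
    rng=None,
) -> BlankRecord:
    """Medium-only blank of one vial on the rig (experiment-start reference)."""
    reads = [vr.measure_raw(optics, vial, None, rng, noise=noise) for _ in range(n_reads)]
    return record_blank(vial.vial_id, reads)


def _position(seed_child, *, led_power: int = 2, od_start: float, doubling_time_h: float = 2.5, stress_factor: float = 1.0):
    rng = np.random.default_rng(seed_child)
    optics = vr.make_optics("S0", led_power)
    vial = vr.TrueVial(
        "V0", glass_offset=float(rng.normal(0.0, vr.DEFAULT_GLASS_OFFSET_SD))
    )
    culture = vr.TrueCulture(
        od_true=od_start, doubling_time_h=doubling_time_h, stress_factor=stress_factor
    )
    return rng, optics, vial, culture


def doubling_time_recovery_study(
    n_seeds: int = 100,
    *,
    seed: int = 0,
    hours: float = 8.0,
    od_start: float = 0.2,
    doubling_time_h: float = 2.5,
    stress_factor: float = 1.0,
    config: ControllerConfig | None = None,
) -> dict:
    """Recover the doubling time through the complete chain, many seeds.

    Per seed: draw a fresh glass vial, calibrate it (noisy, 5 reads/point),
    blank it, then run the turbidostat loop and average the per-segment
    log-linear doubling-time estimates.  Returns the grand mean over seeds
    along with the per-seed values.
    """
    config = config or ControllerConfig()
    per_seed = []
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    for child in children:
        rng, optics, vial, culture = _position(
            child,
            od_start=od_start,
            doubling_time_h=doubling_time_h,
            stress_factor=stress_factor,
        )
        curve = calibrate_position(optics, vial, rng=rng)
        blank = measure_blank(optics, vial, rng=rng)
        loop = VirtualTurbidostat(
            optics, vial, culture, curve, config, blank=blank, rng=rng
        )
        log = loop.run(hours)
        doublings = [
            e.doubling_time_h for e in log.estimates if e.doubling_time_h is not None
        ]
        if doublings:
            per_seed.append(float(np.mean(doublings)))
    return {
        "mean_doubling_h": float(np.mean(per_seed)),
        "sd_doubling_h": float(np.std(per_seed, ddof=1)),
        "per_seed": per_seed,
        "n_seeds": len(per_seed),
    }


@dataclass
class SoakResult:
    log: ExperimentLog
    ledger: BottleLedger
    fraction_in_band: float
    mean_cycle_h: float
    expected_cycle_h: float

    @property
    def ledger_matches_commanded(self) -> bool:
        return self.ledger.total_consumed_ml() == self.log.total_commanded_ml


def soak_test(
    hours: float = 72.0,
    *,
    seed: int = 0,
    config: ControllerConfig | None = None,
    od_start: float = 0.35,
    doubling_time_h: float = 2.5,
    band: tuple[float, float] = (0.25, 0.55),
) -> SoakResult:
    """Long closed-loop run: band occupancy, cycle period, medium accounting.

    A stable loop keeps the measured OD inside ``band`` essentially always
    and cycles with period doubling_time * log2(ht/lt).  Commanded medium is
    mirrored into a bottle ledger and must reconcile exactly.
    """
    config = config or ControllerConfig()
    rng, optics, vial, culture = _position(
        np.random.SeedSequence(seed), od_start=od_start, doubling_time_h=doubling_time_h
    )
    curve = calibrate_position(optics, vial, rng=rng)
    blank = measure_blank(optics, vial, rng=rng)
    ledger = BottleLedger()
    ledger.add_bottle(Bottle("B0", medium="EMM", start_weight_g=20000.0))
    ledger.assign(vial.vial_id, "B0")
    loop = VirtualTurbidostat(
        optics, vial, culture, curve, config, blank=blank, rng=rng, ledger=ledger
    )
    log = loop.run(hours)
    ods = log.ods
    lo, hi = band
    fraction = float(np.mean((ods >= lo) & (ods <= hi)))
    starts = [e.t_start_h for e in log.events]
    cycles = np.diff(starts[1:])  # drop the approach from the start OD
    mean_cycle = float(np.mean(cycles)) if cycles.size else float("nan")
    expected = doubling_time_h * np.log2(config.ht / config.lt)
    return SoakResult(
        log=log,
        ledger=ledger,
        fraction_in_band=fraction,
        mean_cycle_h=mean_cycle,
        expected_cycle_h=float(expected),
    )


def vial_swap_study(
    *,
    seed: int = 0,
    offset_shift: float = 500.0,
    od_true: float = 0.35,
    n_reads: int = 5,
) -> dict:
    """Error cured by a blank reset after a vial swap.

    Calibrate and blank vial A, swap in vial B whose glass offset differs by
    ``offset_shift`` raw units, put a culture of known OD in it, and compare
    the reported OD against truth (a) still using A's blank and (b) after
    resetting the blank on B's medium reads.  The delta-raw method makes (b)
    exact up to read noise; (a) carries the full offset through the curve.
    """
    rng, optics, vial_a, _ = _position(np.random.SeedSequence(seed), od_start=od_true)
    curve = calibrate_position(optics, vial_a, rng=rng)
    blank_a = measure_blank(optics, vial_a, rng=rng)
    vial_b = vr.swap_vial(
        vial_a, new_offset=vial_a.glass_offset + offset_shift, new_id=vial_a.vial_id
    )
    culture = vr.TrueCulture(od_true=od_true)

    def median_od(blank):
        reads = [vr.measure_raw(optics, vial_b, culture, rng) for _ in range(n_reads)]
        return float(
            np.median([compute_od(r, blank, curve).od for r in reads])
        )

    od_stale = median_od(blank_a)
    session = ReplacementSession(
        vial_id=vial_a.vial_id, raw_blank_old=blank_a.raw_blank
    )
    medium_reads = [
        vr.measure_raw(optics, vial_b, None, rng) for _ in range(n_reads)
    ]
    blank_b = reset_blank(session, medium_reads)
    od_fresh = median_od(blank_b)
    return {
        "od_true": od_true,
        "od_stale_blank": od_stale,
        "od_after_reset": od_fresh,
        "error_stale": abs(od_stale - od_true),
        "error_after_reset": abs(od_fresh - od_true),
        "session": session,
    }
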