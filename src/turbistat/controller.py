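"""Turbidostat feedback loop: threshold-triggered dilution, dilution-efficiency
accounting, and growth-rate estimation between dilutions.

The culture oscillates between a low and a high OD threshold (LT, HT).  When
a reading reaches HT the influx pump injects medium (efflux holds the volume)
until the culture is back at LT; the number of dilution rounds needed to get
there is recorded as an efficiency diagnostic — a healthy position needs one
round, a clogged or leaking line needs more.  The exponential growth rate is
fitted by ordinary least squares on ln(OD) vs time over each inter-dilution
segment, and smoothed with a trailing window of 10 estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import virtualrig as vr
from .calibration import CalibrationCurve
from .od_engine import BlankRecord, ODReading, compute_od, record_blank

__all__ = [
    "ControllerConfig",
    "DilutionEvent",
    "GrowthEstimate",
    "should_dilute",
    "dilution_volume",
    "run_dilution",
    "estimate_growth",
    "window_average",
    "VirtualTurbidostat",
    "ExperimentLog",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Turbidostat loop parameters for one vial."""

    ht: float = 0.5  # high OD threshold: dilution trigger (inclusive)
    lt: float = 0.3  # low OD threshold: dilution target
    vial_volume_ml: float = 25.0
    influx_flow_ml_per_s: float = 1.0
    max_rounds: int = 5
    settle_time_s: float = 60.0
    window: int = 10  # sliding window (points) for growth-rate smoothing
    lt_tolerance_od: float = 0.01  # stop diluting once od <= lt + tolerance
    max_bolus_fraction: float = 0.4  # per-round bolus cap, fraction of vial volume
    min_points: int = 5  # minimum readings for a growth fit
    cadence_s: float = vr.DEFAULT_CADENCE_S

    def __post_init__(self):
        if not (0 < self.lt < self.ht):
            raise ValueError("thresholds must satisfy 0 < lt < ht")
        if self.influx_flow_ml_per_s <= 0:
            raise ValueError("influx flow must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass(frozen=True)
class DilutionEvent:
    vial_id: str
    t_start_h: float
    t_end_h: float
    od_before: float
    od_after: float
    commanded_volume_ml: float
    rounds: int
    failed: bool = False  # max_rounds exhausted without reaching the target


@dataclass(frozen=True)
class GrowthEstimate:
    vial_id: str
    interval_h: tuple[float, float]
    mu_per_h: float
    r_squared: float
    n_points: int
    n_excluded: int = 0  # non-positive ODs dropped before the log fit

    @property
    def doubling_time_h(self) -> float | None:
        if self.mu_per_h <= 0:
            return None
        return math.log(2.0) / self.mu_per_h


def should_dilute(od: float, config: ControllerConfig) -> bool:
    """Trigger at or above the high threshold (inclusive at HT)."""
    return od >= config.ht


def dilution_volume(od_now: float, lt: float, vial_volume_ml: float) -> float:
    """Medium volume taking the culture from od_now to lt under bolus dilution.

    Mass balance at constant vessel volume: od_now*V = lt*(V + v), so
    v = V*(od_now/lt - 1).
    """
    if od_now <= lt:
        raise ValueError(f"od_now ({od_now}) must exceed the low threshold ({lt})")
    return vial_volume_ml * (od_now / lt - 1.0)


def run_dilution(
    vial_id: str,
    od_now: float,
    config: ControllerConfig,
    dispense: Callable[[float], float],
    remeasure: Callable[[], float],
    *,
    t_start_h: float = 0.0,
) -> DilutionEvent:
    """Dilute towards LT, re-measuring after each bolus; count the rounds.

    ``dispense(v_ml)`` delivers a bolus and returns the elapsed time in hours
    (pumping plus settling); ``remeasure()`` returns the post-settle OD.  The
    per-round bolus is capped at ``max_bolus_fraction`` of the vial volume, so
    large HT/LT ratios legitimately take more than one round.  Exhausting
    ``max_rounds`` marks the event failed (pump or efflux fault, or a leak).
    """
    od = od_now
    t = t_start_h
    total_v = 0.0
    rounds = 0
    target = config.lt + config.lt_tolerance_od
    while od > target and rounds < config.max_rounds:
        v = min(
            dilution_volume(od, config.lt, config.vial_volume_ml),
            config.max_bolus_fraction * config.vial_volume_ml,
        )
        t += dispense(v)
        total_v += v
        od = remeasure()
        rounds += 1
    return DilutionEvent(
        vial_id=vial_id,
        t_start_h=t_start_h,
        t_end_h=t,
        od_before=od_now,
        od_after=od,
        commanded_volume_ml=total_v,
        rounds=rounds,
        failed=od > target,
    )


def estimate_growth(
    times_h: Sequence[float],
    ods: Sequence[float],
    *,
    vial_id: str = "",
    min_points: int = 5,
) -> GrowthEstimate:
    """OLS fit of ln(OD) vs time over one inter-dilution segment.

    mu is the fitted slope (per hour); the doubling time is ln2/mu.
    Non-positive ODs (possible at the noise floor) are excluded and counted.
    """
    t = np.asarray(list(times_h), dtype=float)
    od = np.asarray(list(ods), dtype=float)
    keep = od > 0
    n_excluded = int((~keep).sum())
    t, od = t[keep], od[keep]
    if t.size < min_points:
        raise ValueError(
            f"growth fit needs >= {min_points} positive-OD readings, got {t.size}"
        )
    log_od = np.log(od)
    if np.allclose(log_od, log_od[0]):
        mu, r2 = 0.0, 1.0
    else:
        fit = stats.linregress(t, log_od)
        mu, r2 = float(fit.slope), float(fit.rvalue**2)
    return GrowthEstimate(
        vial_id=vial_id,
        interval_h=(float(t[0]), float(t[-1])),
        mu_per_h=mu,
        r_squared=r2,
        n_points=int(t.size),
        n_excluded=n_excluded,
    )


def window_average(values: Sequence[float], window: int = 10) -> np.ndarray:
    """Trailing mean over the last ``window`` values; prefixes use what exists."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(list(values), dtype=float)
    return s.rolling(window, min_periods=1).mean().to_numpy()


# ---------------------------------------------------------------------------
# Closed loop against the virtual rig


@dataclass
class ExperimentLog:
    vial_id: str
    readings: list[ODReading] = field(default_factory=list)
    od_true: list[float] = field(default_factory=list)
    times_h: list[float] = field(default_factory=list)
    events: list[DilutionEvent] = field(default_factory=list)
    estimates: list[GrowthEstimate] = field(default_factory=list)

    @property
    def ods(self) -> np.ndarray:
        return np.array([r.od for r in self.readings])

    @property
    def total_commanded_ml(self) -> float:
        return sum(e.commanded_volume_ml for e in self.events)

    def smoothed_mu(self, window: int = 10) -> np.ndarray:
        return window_average([e.mu_per_h for e in self.estimates], window)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_h": self.times_h,
                "raw": [r.raw_t for r in self.readings],
                "delta_raw": [r.delta_raw for r in self.readings],
                "od": [r.od for r in self.readings],
                "od_true": self.od_true,
            }
        )


class VirtualTurbidostat:
    """Threshold-triggered dilution loop running one vial on the virtual rig.

    Wires the simulator, the calibration curve, the delta-raw OD engine and
    the controller into a closed loop: measure every cadence tick, dilute on
    HT crossings, fit growth on each completed inter-dilution segment
    (excluding a settle window after dilution so pump transients do not bias
    the fit).  Consumption can be mirrored into a bottle ledger, and failed
    dilutions are reported to an alert sink.
    """

    def __init__(
        self,
        optics: vr.TrueOptics,
        vial: vr.TrueVial,
        culture: vr.TrueCulture,
        curve: CalibrationCurve,
        config: ControllerConfig,
        *,
        blank: BlankRecord | None = None,
        rng=None,
        influx_efficiency: float = 1.0,
        ledger=None,
        on_dilution_failure: Callable[[DilutionEvent], None] | None = None,
    ):
        self.optics = optics
        self.vial = vial
        self.culture = culture
        self.curve = curve
        self.config = config
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        if not (0.0 <= influx_efficiency <= 1.0):
            raise ValueError("influx_efficiency must be in [0, 1]")
        self.influx_efficiency = influx_efficiency
        self.ledger = ledger
        self.on_dilution_failure = on_dilution_failure
        if blank is None:
            # medium-only blank on the experiment vial before inoculation
            reads = [
                vr.measure_raw(optics, vial, None, self.rng) for _ in range(5)
            ]
            blank = record_blank(vial.vial_id, reads)
        self.blank = blank
        self.t_h = 0.0
        self.log = ExperimentLog(vial_id=vial.vial_id)
        self._segment_start_h = 0.0
        self._segment_growth_from_h = 0.0  # first usable time for the growth fit

    # -- internals ----------------------------------------------------------

    def _measure_od(self) -> ODReading:
        raw = vr.measure_raw(self.optics, self.vial, self.culture, self.rng)
        return compute_od(raw, self.blank, self.curve)

    def _dispense(self, v_ml: float) -> float:
        """Deliver a bolus (with pump efficiency) and let the culture settle."""
        delivered = v_ml * self.influx_efficiency
        self.culture = vr.bolus_dilute(self.vial, self.culture, delivered)
        elapsed_h = (
            v_ml / self.config.influx_flow_ml_per_s + self.config.settle_time_s
        ) / 3600.0
        self.culture = vr.advance(self.culture, elapsed_h)
        self.t_h += elapsed_h
        return elapsed_h

    def _fit_segment(self, t_end_h: float) -> None:
        lo = self._segment_growth_from_h
        pts = [
            (t, r.od)
            for t, r in zip(self.log.times_h, self.log.readings)
            if lo <= t <= t_end_h and r.od > 0
        ]
        if len(pts) >= self.config.min_points:
            t, od = zip(*pts)
            self.log.estimates.append(
                estimate_growth(
                    t, od, vial_id=self.vial.vial_id, min_points=self.config.min_points
                )
            )

    # -- public loop --------------------------------------------------------

    def step(self) -> ODReading:
        """One cadence tick: grow, measure, maybe dilute."""
        reading = self._measure_od()
        self.log.times_h.append(self.t_h)
        self.log.readings.append(reading)
        self.log.od_true.append(self.culture.od_true)
        if should_dilute(reading.od, self.config):
            self._fit_segment(self.t_h)
            event = run_dilution(
                self.vial.vial_id,
                reading.od,
                self.config,
                self._dispense,
                lambda: self._measure_od().od,
                t_start_h=self.t_h,
            )
            self.log.events.append(event)
            if self.ledger is not None:
                self.ledger.record_consumption(event)
            if event.failed and self.on_dilution_failure is not None:
                self.on_dilution_failure(event)
            self.t_h = event.t_end_h
            self._segment_start_h = self.t_h
            self._segment_growth_from_h = self.t_h + self.config.settle_time_s / 3600.0
        dt_h = self.config.cadence_s / 3600.0
        self.culture = vr.advance(self.culture, dt_h)
        self.t_h += dt_h
        return reading

    def run(self, hours: float) -> ExperimentLog:
        while self.t_h < hours:
            self.step()
        self._fit_segment(self.t_h)  # trailing partial segment
        return self.log
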