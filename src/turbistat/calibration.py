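"""Fixed-vial OD calibration: inoculation planning, stock back-calculation,
dataset correction, monotone curve fitting, LED-power selection, temperature
calibration and calibration-store management.

The protocol calibrates each sleeve with a single fixed glass vial: a first
PBS-only measurement (the anchor ``raw_0_cal``), then successive inoculations
of a concentrated stock culture to step the vial through increasing ODs.  The
stock's true OD is back-calculated afterwards from endpoint spectrophotometer
measurements and the cumulative dilution factor, and every calibration-point
OD is rescaled accordingly before the curve is fitted.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._curves import logistic4, logistic4_deriv, logistic4_inverse, raw_domain

__all__ = [
    "InoculationStep",
    "InoculationPlan",
    "CalibrationPoint",
    "CalibrationDataset",
    "CalibrationCurve",
    "TempCalPlan",
    "plan_inoculation",
    "default_target_ods",
    "backcalculate_stock",
    "correct_calibration",
    "fit_curve",
    "select_led_power",
    "plan_temp_calibration",
    "fit_temp_map",
    "commanded_temperature",
    "CalibrationStore",
    "REFERENCE_MEDIA_SCATTERING",
    "media_equivalence_report",
    "check_media_equivalence",
]


# ---------------------------------------------------------------------------
# Inoculation planning


@dataclass(frozen=True)
class InoculationStep:
    added_volume_ml: float
    cumulative_stock_volume_ml: float
    cumulative_fraction: float
    nominal_od: float


@dataclass(frozen=True)
class InoculationPlan:
    """Successive stock additions stepping one vial through the calibration ODs.

    Step 0 is always the PBS-only measurement (fraction 0, OD 0).  With the
    vial initially holding ``vial_volume_ml`` of PBS and a cumulative stock
    volume v, the stock fraction is v / (vial_volume + v) and the nominal OD
    is stock_od_nominal times that fraction.
    """

    vial_volume_ml: float
    stock_od_nominal: float
    steps: tuple[InoculationStep, ...]

    @property
    def final_fraction(self) -> float:
        return self.steps[-1].cumulative_fraction

    @property
    def nominal_ods(self) -> np.ndarray:
        return np.array([s.nominal_od for s in self.steps])

    @property
    def cumulative_fractions(self) -> np.ndarray:
        return np.array([s.cumulative_fraction for s in self.steps])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.steps])


def default_target_ods(n_points: int = 10, max_od: float = 0.8) -> list[float]:
    """PBS zero plus geometrically spaced targets up to ``max_od``.

    Geometric spacing concentrates points where the scattering curve bends.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points (PBS + one culture OD)")
    tail = np.geomspace(0.05, max_od, n_points - 1)
    return [0.0] + [round(float(v), 4) for v in tail]


def plan_inoculation(
    target_ods: Sequence[float],
    vial_volume_ml: float,
    stock_od_nominal: float,
    *,
    min_stock_ratio: float = 20.0,
) -> InoculationPlan:
    """Compute per-step stock volumes so nominal ODs hit the targets.

    Accounts for the vial volume growing with each addition: the cumulative
    stock volume for target OD t solves  S*v/(V+v) = t,  i.e.
    v = t*V/(S-t).  The stock must be concentrated (default >= 20x the top
    target) so the total added volume stays small next to the vial volume.
    """
    targets = [float(t) for t in target_ods]
    if not targets:
        raise ValueError("target_ods is empty")
    if targets[0] != 0.0:
        targets = [0.0] + targets
    if any(b < a for a, b in zip(targets, targets[1:])):
        raise ValueError("target ODs must be non-decreasing (dilution cannot remove cells)")
    if vial_volume_ml <= 0:
        raise ValueError("vial_volume_ml must be > 0")
    top = max(targets)
    if top > 0 and stock_od_nominal < min_stock_ratio * top:
        raise ValueError(
            f"stock OD {stock_od_nominal} too dilute: must be >= {min_stock_ratio}x "
            f"the top target ({top}) to keep added volume small"
        )
    steps = []
    prev_v = 0.0
    for t in targets:
        v = t * vial_volume_ml / (stock_od_nominal - t) if t > 0 else 0.0
        steps.append(
            InoculationStep(
                added_volume_ml=v - prev_v,
                cumulative_stock_volume_ml=v,
                cumulative_fraction=v / (vial_volume_ml + v) if v > 0 else 0.0,
                nominal_od=t,
            )
        )
        prev_v = v
    return InoculationPlan(vial_volume_ml, stock_od_nominal, tuple(steps))


# ---------------------------------------------------------------------------
# Calibration datasets


@dataclass
class CalibrationPoint:
    raw_mean: float
    raw_sd: float
    nominal_od: float
    corrected_od: float | None = None

    @property
    def od(self) -> float:
        """Best available OD: corrected if present, else nominal."""
        return self.nominal_od if self.corrected_od is None else self.corrected_od


@dataclass
class CalibrationDataset:
    """Per-sleeve calibration table acquired with one fixed vial.

    Point 0 is the PBS measurement; its raw mean is the anchor ``raw_0_cal``.
    """

    sleeve_id: str
    vial_id: str
    led_power: int
    points: list[CalibrationPoint]
    corrected: bool = False
    monotone_ok: bool = True

    def __post_init__(self):
        if not self.points:
            raise ValueError("dataset has no points")
        if self.points[0].nominal_od != 0.0:
            raise ValueError("point 0 must be the PBS point (OD 0)")

    @property
    def raw_0_cal(self) -> float:
        return self.points[0].raw_mean

    @property
    def ods(self) -> np.ndarray:
        return np.array([p.od for p in self.points])

    @property
    def raw_means(self) -> np.ndarray:
        return np.array([p.raw_mean for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sleeve_id": self.sleeve_id,
                "vial_id": self.vial_id,
                "led_power": self.led_power,
                "point_index": i,
                "raw_mean": p.raw_mean,
                "raw_sd": p.raw_sd,
                "nominal_od": p.nominal_od,
                "corrected_od": p.corrected_od,
            }
            for i, p in enumerate(self.points)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CalibrationDataset":
        df = pd.read_csv(path, sep="\t").sort_values("point_index")
        points = [
            CalibrationPoint(
                raw_mean=float(r.raw_mean),
                raw_sd=float(r.raw_sd),
                nominal_od=float(r.nominal_od),
                corrected_od=None if pd.isna(r.corrected_od) else float(r.corrected_od),
            )
            for r in df.itertuples()
        ]
        first = df.iloc[0]
        return cls(
            sleeve_id=str(first.sleeve_id),
            vial_id=str(first.vial_id),
            led_power=int(first.led_power),
            points=points,
            corrected=all(p.corrected_od is not None for p in points),
        )


def backcalculate_stock(
    plan: InoculationPlan, measured_final_ods: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Infer the true stock OD from endpoint spectrophotometer readings.

    The endpoint OD of each vial that shared this stock equals
    stock_od_actual * final cumulative fraction, so

        stock_od_actual = mean(measured endpoint ODs) / final_fraction

    and every calibration-point OD is rescaled to
    stock_od_actual * cumulative_fraction_i.  Vials fed from distinct stocks
    must be averaged separately (one call per stock).
    """
    measured = np.asarray(list(measured_final_ods), dtype=float)
    if measured.size == 0:
        raise ValueError("no endpoint OD measurements supplied")
    if plan.final_fraction <= 0:
        raise ValueError("plan has zero final stock fraction; nothing to back-calculate")
    stock_od_actual = float(measured.mean()) / plan.final_fraction
    corrected = stock_od_actual * plan.cumulative_fractions
    return stock_od_actual, corrected


def correct_calibration(
    dataset: CalibrationDataset, corrected_ods: Sequence[float]
) -> CalibrationDataset:
    """Replace nominal ODs with back-calculated ones; order is preserved.

    With the fixed-vial protocol every sleeve measures the points in the same
    order, so the legacy re-ordering step (undoing the 16-vial rotational
    permutation) is an explicit identity here.  Monotonicity of raw vs OD is
    checked and violations beyond noise are flagged, not fatal.
    """
    corrected = np.asarray(list(corrected_ods), dtype=float)
    if corrected.size != len(dataset.points):
        raise ValueError(
            f"{corrected.size} corrected ODs for {len(dataset.points)} points"
        )
    if corrected[0] != 0.0:
        raise ValueError("point 0 must stay the PBS point (corrected OD 0)")
    points = [
        dataclasses.replace(p, corrected_od=float(od))
        for p, od in zip(dataset.points, corrected)
    ]
    new = dataclasses.replace(dataset, points=points, corrected=True)
    # flag non-monotone raw vs OD beyond what read noise explains
    raws = new.raw_means
    sds = np.array([p.raw_sd for p in new.points])
    tol = 3.0 * float(np.max(sds)) if np.any(sds > 0) else 0.0
    diffs = np.diff(raws)
    direction = -1.0 if raws[-1] < raws[0] else 1.0
    if np.any(direction * diffs < -tol):
        new.monotone_ok = False
        warnings.warn(
            f"calibration data for sleeve {new.sleeve_id} not monotone beyond "
            "noise; check inoculation steps",
            stacklevel=2,
        )
    return new


# ---------------------------------------------------------------------------
# Curve fitting


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted monotone map between raw scattering and OD for one sleeve/vial.

    ``params = (a, b, c, d)`` are the least-squares parameters of
    raw = a + b/(1 + exp((od - c)/d)); the OD lookup f(raw) is the analytic
    inverse od = c + d*ln(b/(raw - a) - 1).  ``raw_0_cal`` anchors the
    delta-raw OD computation during experiments.
    """

    sleeve_id: str
    vial_id: str
    params: tuple[float, float, float, float]
    raw_0_cal: float
    valid_raw_range: tuple[float, float]
    od_range: tuple[float, float]
    rmse_raw: float
    max_od_residual: float

    def od_from_raw(self, raw: float) -> float:
        return float(logistic4_inverse(raw, *self.params))

    def raw_from_od(self, od: float) -> float:
        return float(logistic4(od, *self.params))

    def d_raw_d_od(self, od) -> float:
        return logistic4_deriv(od, *self.params)

    def min_abs_slope(self, window: tuple[float, float] = (0.2, 0.5)) -> float:
        lo, hi = window
        return min(abs(self.d_raw_d_od(lo)), abs(self.d_raw_d_od(hi)))

    def in_valid_range(self, raw: float) -> bool:
        lo, hi = self.valid_raw_range
        return lo <= raw <= hi

    def hard_raw_limits(self) -> tuple[float, float]:
        """Open interval outside of which the inverse map does not exist."""
        return raw_domain(self.params[0], self.params[1])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationCurve":
        d = dict(d)
        for key in ("params", "valid_raw_range", "od_range"):
            d[key] = tuple(d[key])
        return cls(**d)


def fit_curve(
    dataset: CalibrationDataset,
    *,
    range_margin: float = 0.02,
    zero_tolerance_od: float = 0.02,
) -> CalibrationCurve:
    """Least-squares fit of the 4-parameter monotone logistic to one dataset.

    Initialisation is deterministic, from data quantiles, so refitting the
    same points reproduces identical parameters.  The valid raw range is the
    fitted raw span of the data extended by ``range_margin`` of the span on
    each side (readings slightly past the calibrated ODs are extrapolation,
    flagged downstream rather than refused).
    """
    if len(dataset.points) < 5:
        raise ValueError("need >= 5 calibration points to fit the curve")
    od = dataset.ods
    raw = dataset.raw_means
    span = float(raw.max() - raw.min())
    if span == 0:
        raise ValueError("degenerate calibration data: constant raw values")
    decreasing = raw[np.argmax(od)] < raw[np.argmin(od)]
    # `a` is the large-OD asymptote, `a+b` the OD->-inf asymptote; place both
    # just outside the observed raw span on the appropriate sides
    if decreasing:
        a0, b0 = float(raw.min() - 0.1 * span), span * 1.2
    else:
        a0, b0 = float(raw.max() + 0.1 * span), -span * 1.2
    c0 = float(np.median(od))
    d0 = max(float(od.max() - od.min()) / 4.0, 1e-3)
    try:
        params, _ = curve_fit(
            logistic4,
            od,
            raw,
            p0=(a0, b0, c0, d0),
            bounds=(
                (-np.inf, -np.inf, -np.inf, 1e-6),
                (np.inf, np.inf, np.inf, np.inf),
            ),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"calibration fit for sleeve {dataset.sleeve_id} did not converge: "
            f"{err}; points={list(zip(od, raw))}"
        ) from err
    params = tuple(float(p) for p in params)
    fitted = logistic4(od, *params)
    rmse = float(np.sqrt(np.mean((fitted - raw) ** 2)))
    lo_raw, hi_raw = raw_domain(params[0], params[1])
    inside = (raw > lo_raw) & (raw < hi_raw)
    if not np.all(inside):
        warnings.warn(
            f"{int((~inside).sum())} calibration raw mean(s) outside the fitted "
            "curve's invertible range; data may be non-monotone",
            stacklevel=2,
        )
    od_resid = np.abs(
        np.array(
            [
                logistic4_inverse(r, *params) - o
                for r, o in zip(raw[inside], od[inside])
            ]
        )
    )
    max_od_resid = float(od_resid.max()) if od_resid.size else math.inf
    raw_lo = float(logistic4(od.max(), *params))
    raw_hi = float(logistic4(od.min(), *params))
    raw_lo, raw_hi = min(raw_lo, raw_hi), max(raw_lo, raw_hi)
    margin = range_margin * (raw_hi - raw_lo)
    valid = (max(raw_lo - margin, lo_raw + 1e-9), min(raw_hi + margin, hi_raw - 1e-9))
    curve = CalibrationCurve(
        sleeve_id=dataset.sleeve_id,
        vial_id=dataset.vial_id,
        params=params,
        raw_0_cal=dataset.raw_0_cal,
        valid_raw_range=valid,
        od_range=(float(od.min()), float(od.max())),
        rmse_raw=rmse,
        max_od_residual=max_od_resid,
    )
    od_at_anchor = curve.od_from_raw(curve.raw_0_cal)
    if abs(od_at_anchor) > zero_tolerance_od:
        warnings.warn(
            f"curve OD at raw_0_cal is {od_at_anchor:.4f}, further from 0 than "
            f"{zero_tolerance_od}; calibration data may be inconsistent",
            stacklevel=2,
        )
    return curve


def select_led_power(
    curves_by_power: Mapping[int, CalibrationCurve],
    od_window: tuple[float, float] = (0.2, 0.5),
) -> int:
    """Pick the LED power whose curve has the largest worst-case |d raw/d OD|
    over the working OD window; ties go to the lower power."""
    if not curves_by_power:
        raise ValueError("no candidate LED powers")
    lo, hi = od_window
    usable = {
        p: c
        for p, c in curves_by_power.items()
        if c.od_range[0] <= lo and c.od_range[1] >= hi
    }
    if not usable:
        raise ValueError(
            f"OD window {od_window} outside every candidate curve's fitted range"
        )
    best_power, best_slope = None, -math.inf
    for power in sorted(usable):
        slope = usable[power].min_abs_slope(od_window)
        if slope > best_slope:  # strict: equal slope keeps the lower power
            best_power, best_slope = power, slope
    return best_power


# ---------------------------------------------------------------------------
# Temperature calibration


@dataclass
class TempCalPlan:
    """Three-point sleeve temperature calibration: RT, RT+6, RT+12.

    The elevations keep the top setpoint inside the physiological range of
    yeast growth (25-32 C) and reachable by the heaters even in warm rooms.
    ``offset_c`` is an optional constant correction for the residual gap
    between the sleeve-derived temperature and an in-culture reference probe
    (cultures run slightly cooler than the target, ~0.15 C on real rigs).
    """

    room_temp_c: float
    setpoints_c: tuple[float, float, float]
    offset_c: float = 0.0
    pairs: list[tuple[float, float]] = field(default_factory=list)
    slope: float | None = None
    intercept: float | None = None


def plan_temp_calibration(
    room_temp_c: float,
    *,
    elevations_c: tuple[float, float, float] = (0.0, 6.0, 12.0),
    offset_c: float = 0.0,
) -> TempCalPlan:
    if tuple(elevations_c) != (0.0, 6.0, 12.0):
        raise ValueError("temperature calibration uses elevations 0, +6, +12 C")
    setpoints = tuple(room_temp_c + e for e in elevations_c)
    return TempCalPlan(room_temp_c=room_temp_c, setpoints_c=setpoints, offset_c=offset_c)


def fit_temp_map(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """OLS line mapping sleeve-surface reading to culture temperature.

    ``pairs`` are (surface_temp, reference_temp) at the three stabilised
    setpoints.  Returns (slope, intercept); slope must come out positive.
    """
    if len(pairs) < 3:
        raise ValueError("need the three calibration pairs (RT, RT+6, RT+12)")
    surface = np.array([p[0] for p in pairs], dtype=float)
    reference = np.array([p[1] for p in pairs], dtype=float)
    if np.any(np.diff(reference) <= 0):
        raise ValueError("reference temperatures must be strictly increasing")
    slope, intercept = np.polyfit(surface, reference, 1)
    if slope <= 0:
        raise ValueError(f"non-physical fitted slope {slope:.3f}")
    return float(slope), float(intercept)


def commanded_temperature(requested_c: float, offset_c: float = 0.0) -> float:
    """Target to command so the culture sits at the requested temperature.

    Cultures equilibrate slightly below the commanded target; commanding
    requested + offset compensates.
    """
    return requested_c + offset_c


# ---------------------------------------------------------------------------
# Calibration store


class CalibrationStore:
    """JSON-backed store of fitted calibration curves.

    One calibration is tied to one experiment; stale entries are deleted once
    their experiment ends.  Deletion is refused while any active experiment
    references the entry.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._entries: dict[str, dict] = {}
        if self.path is not None and self.path.exists():
            self._entries = json.loads(self.path.read_text())

    def _persist(self):
        if self.path is not None:
            self.path.write_text(json.dumps(self._entries, indent=1, sort_keys=True))

    def add(self, curve: CalibrationCurve, calibration_id: str | None = None) -> str:
        if calibration_id is None:
            stamp = datetime.now(timezone.utc).strftime("%Y%m%dT%H%M%S")
            calibration_id = f"{curve.sleeve_id}:{curve.vial_id}:{stamp}"
        if calibration_id in self._entries:
            raise KeyError(f"calibration id already present: {calibration_id}")
        self._entries[calibration_id] = {
            "curve": curve.to_dict(),
            "created": datetime.now(timezone.utc).isoformat(),
        }
        self._persist()
        return calibration_id

    def get(self, calibration_id: str) -> CalibrationCurve:
        try:
            return CalibrationCurve.from_dict(self._entries[calibration_id]["curve"])
        except KeyError:
            raise KeyError(f"unknown calibration id: {calibration_id}") from None

    def ids(self) -> list[str]:
        return sorted(self._entries)

    def delete(self, calibration_id: str, in_use: Sequence[str] = ()) -> None:
        if calibration_id not in self._entries:
            raise KeyError(f"unknown calibration id: {calibration_id}")
        if calibration_id in set(in_use):
            raise ValueError(
                f"calibration {calibration_id} is referenced by an active "
                "experiment; stop the experiment before deleting it"
            )
        del self._entries[calibration_id]
        self._persist()


# ---------------------------------------------------------------------------
# Media / PBS scattering equivalence

#: Reference fixed-vial scattering scans of calibration liquids and fission
#: yeast media on one sleeve: mean and SD of 5 consecutive raw reads, plus
#: spectrophotometer OD595 against a water blank.  PBS is the calibration
#: liquid; EMM minimal, EMM6S supplemented minimal, YE4S rich medium.
REFERENCE_MEDIA_SCATTERING: dict[str, dict[str, float | None]] = {
    "water": {"raw_mean": 41295.0, "raw_sd": 33.0, "od595": None},
    "PBS": {"raw_mean": 41115.0, "raw_sd": 30.0, "od595": 0.00},
    "EMM": {"raw_mean": 41652.0, "raw_sd": 54.0, "od595": 0.00},
    "EMM6S": {"raw_mean": 41362.0, "raw_sd": 79.0, "od595": 0.00},
    "YE4S": {"raw_mean": 41457.0, "raw_sd": 66.0, "od595": 0.03},
}


def media_equivalence_report(
    scans: Mapping[str, Mapping[str, float | None]] | None = None,
    reference: str = "water",
) -> pd.DataFrame:
    """Water-referenced differences of per-medium raw scattering averages.

    Columns: raw_mean, raw_sd, diff_raw (mean minus the reference liquid's
    mean), od595 where measured.  Used to confirm that the media a strain
    grows in scatter like PBS to within read noise, the premise that lets a
    PBS calibration anchor and a medium blank share one delta-raw scale.
    """
    scans = REFERENCE_MEDIA_SCATTERING if scans is None else scans
    if reference not in scans:
        raise KeyError(f"reference liquid {reference!r} not in scans")
    ref_mean = float(scans[reference]["raw_mean"])
    rows = {}
    for name, stats in scans.items():
        rows[name] = {
            "raw_mean": float(stats["raw_mean"]),
            "raw_sd": float(stats["raw_sd"]),
            "diff_raw": float(stats["raw_mean"]) - ref_mean,
            "od595": stats.get("od595"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def check_media_equivalence(
    raw_pbs: float, raw_medium: float, noise_sd: float, factor: float = 3.0
) -> bool:
    """True when PBS and medium scattering agree to within ``factor`` x noise."""
    return abs(raw_pbs - raw_medium) < factor * noise_sd
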