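"""Virtual culture/optics rig: ground truth for testing the control stack without hardware.

Emulates the measurement phenomenology of a smart-sleeve turbidostat position:

* a monotone saturating map from true OD to raw light scattering, whose
  steepness over the working OD window grows with LED power;
* an additive per-glass-vial offset on the raw signal, re-drawn by rotation
  or vial-swap events (glass imperfections dominate vial-to-vial variability);
* Gaussian read noise on the raw channel;
* pure exponential growth between pump events, optionally slowed by a
  stress factor;
* bolus dilution at constant vessel volume (influx matched by efflux).

Every stochastic draw flows through an explicit :class:`numpy.random.Generator`
so simulated datasets are exactly replayable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._curves import logistic4, logistic4_deriv, logistic4_inverse

__all__ = [
    "TrueOptics",
    "TrueVial",
    "TrueCulture",
    "make_optics",
    "advance",
    "measure_raw",
    "rotate",
    "swap_vial",
    "bolus_dilute",
    "simulate_trace",
    "write_trajectory",
    "Scenario",
    "DEFAULT_NOISE_SD",
    "DEFAULT_GLASS_OFFSET_SD",
    "DEFAULT_ROTATION_SD",
    "DEFAULT_CADENCE_S",
]

#: Read noise on the raw channel, in raw units.  Chosen so that the standard
#: deviation of repeated fixed-vial reads falls in the 30-79 band observed on
#: real sleeves across water/PBS/media scans.
DEFAULT_NOISE_SD = 50.0
#: Spread of the per-vial additive glass offset across vials (raw units).
DEFAULT_GLASS_OFFSET_SD = 250.0
#: Step size of the offset re-draw when a vial is rotated a few degrees.
#: Rotation re-samples the same glass-path distribution that distinguishes
#: vials, so the step is set at the vial-to-vial offset scale; this makes the
#: rotated-read variance dominate the fixed-read variance, as seen on hardware.
DEFAULT_ROTATION_SD = 250.0
#: Sampling cadence of the OD channel (447 points in 2 h ~= 16 s).
DEFAULT_CADENCE_S = 16.0


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class TrueOptics:
    """Ground-truth optics of one sleeve at one LED power.

    ``curve_params = (a, b, c, d)`` parameterise the monotone logistic
    raw = a + b/(1 + exp((od - c)/d)); raw decreases with OD for b > 0.
    """

    sleeve_id: str
    led_power: int
    curve_params: tuple[float, float, float, float]
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        a, b, c, d = self.curve_params
        if d <= 0 or b == 0:
            raise ValueError("curve must be strictly monotone (d > 0, b != 0)")

    def g(self, od):
        """True raw value at a given OD (no vial offset, no noise)."""
        return logistic4(od, *self.curve_params)

    def g_inverse(self, raw):
        """True OD at a given raw value."""
        return logistic4_inverse(raw, *self.curve_params)

    def g_deriv(self, od):
        return logistic4_deriv(od, *self.curve_params)

    def min_abs_slope(self, window: tuple[float, float] = (0.2, 0.5)) -> float:
        """Worst-case |d raw/d OD| over an OD window.

        |g'| is unimodal with its peak at od = c, so the minimum over an
        interval is attained at an endpoint.
        """
        lo, hi = window
        return min(abs(self.g_deriv(lo)), abs(self.g_deriv(hi)))


def make_optics(
    sleeve_id: str = "S0",
    led_power: int = 2,
    *,
    floor: float = 30600.0,
    amplitude_per_power: float = 6000.0,
    midpoint_od: float = 0.35,
    scale_od: float = 0.18,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> TrueOptics:
    """Build sleeve optics whose dynamic range scales with LED power.

    The logistic amplitude is ``amplitude_per_power * led_power``, so the
    worst-case slope over any OD window increases strictly with LED power
    (the construction rule the LED-selection logic is validated against).
    Defaults put the OD-zero raw value near 41e3, the scale of real sleeves.
    """
    if led_power < 1:
        raise ValueError("led_power must be >= 1")
    b = amplitude_per_power * float(led_power)
    return TrueOptics(
        sleeve_id=sleeve_id,
        led_power=int(led_power),
        curve_params=(floor, b, midpoint_od, scale_od),
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class TrueVial:
    """One glass culture vessel sitting in a sleeve."""

    vial_id: str
    glass_offset: float = 0.0  # additive, raw units
    rotation_sd: float = DEFAULT_ROTATION_SD
    volume_ml: float = 25.0

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")


@dataclass(frozen=True)
class TrueCulture:
    """True state of the growing population."""

    od_true: float
    doubling_time_h: float = 2.5
    stress_factor: float = 1.0  # in (0, 1]; multiplies the growth rate

    def __post_init__(self):
        if self.od_true < 0:
            raise ValueError("od_true must be >= 0")
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be > 0")
        if not (0 < self.stress_factor <= 1):
            raise ValueError("stress_factor must be in (0, 1]")


def advance(culture: TrueCulture, dt_h: float) -> TrueCulture:
    """Grow the culture exponentially for ``dt_h`` hours."""
    if dt_h < 0:
        raise ValueError("dt_h must be >= 0")
    factor = 2.0 ** (dt_h * culture.stress_factor / culture.doubling_time_h)
    return replace(culture, od_true=culture.od_true * factor)


def measure_raw(
    optics: TrueOptics,
    vial: TrueVial,
    culture: TrueCulture | None,
    rng=None,
    *,
    noise: bool = True,
) -> float:
    """One raw light-scattering read: g(od) + glass offset + Gaussian noise.

    ``culture=None`` measures a medium/PBS-only vial (OD 0).
    """
    od = 0.0 if culture is None else culture.od_true
    eps = 0.0
    if noise:
        eps = _as_rng(rng).normal(0.0, optics.noise_sd)
    return float(optics.g(od)) + vial.glass_offset + eps


def rotate(vial: TrueVial, rng=None) -> TrueVial:
    """Rotate the vial a few degrees: the glass offset takes a random step."""
    if vial.rotation_sd == 0:
        return vial
    delta = _as_rng(rng).normal(0.0, vial.rotation_sd)
    return replace(vial, glass_offset=vial.glass_offset + delta)


def swap_vial(
    vial: TrueVial,
    rng=None,
    *,
    offset_sd: float = DEFAULT_GLASS_OFFSET_SD,
    new_offset: float | None = None,
    new_id: str | None = None,
) -> TrueVial:
    """Replace the glass vial: a fresh offset draw (or an explicit one)."""
    if new_offset is None:
        new_offset = float(_as_rng(rng).normal(0.0, offset_sd))
    return replace(
        vial,
        vial_id=new_id if new_id is not None else vial.vial_id,
        glass_offset=new_offset,
    )


def bolus_dilute(vial: TrueVial, culture: TrueCulture, v_add_ml: float) -> TrueCulture:
    """Instantaneous medium bolus; efflux restores the level, so volume holds.

    od' = od * V / (V + v_add)
    """
    if v_add_ml < 0:
        raise ValueError("v_add_ml must be >= 0")
    factor = vial.volume_ml / (vial.volume_ml + v_add_ml)
    return replace(culture, od_true=culture.od_true * factor)


# ---------------------------------------------------------------------------
# Trace simulation and trajectory files


def simulate_trace(
    optics: TrueOptics,
    vial: TrueVial,
    culture: TrueCulture,
    hours: float,
    *,
    cadence_s: float = DEFAULT_CADENCE_S,
    rng=None,
) -> pd.DataFrame:
    """Free growth (no dilutions): columns t_h, raw, od_true."""
    rng = _as_rng(rng)
    dt_h = cadence_s / 3600.0
    n = int(round(hours / dt_h)) + 1
    rows = []
    for i in range(n):
        rows.append(
            (i * dt_h, measure_raw(optics, vial, culture, rng), culture.od_true)
        )
        culture = advance(culture, dt_h)
    return pd.DataFrame(rows, columns=["t_h", "raw", "od_true"])


def write_trajectory(
    frame: pd.DataFrame,
    path: str | Path,
    vial_id: str,
    start_time: datetime | None = None,
) -> Path:
    """Write a trajectory as TSV: timestamp (ISO-8601), vial_id, raw, od_true."""
    start = start_time or datetime(2000, 1, 1)
    out = pd.DataFrame(
        {
            "timestamp": [
                (start + timedelta(hours=float(t))).isoformat() for t in frame["t_h"]
            ],
            "vial_id": vial_id,
            "raw": frame["raw"].to_numpy(),
            "od_true": frame["od_true"].to_numpy(),
        }
    )
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


def simulate_calibration_run(
    optics: TrueOptics,
    vial: TrueVial,
    plan,
    *,
    stock_od_actual: float | None = None,
    reads_per_point: int = 5,
    spectro_sd: float = 0.0,
    noise: bool = True,
    rng=None,
):
    """Run the fixed-vial calibration protocol on the virtual rig.

    Walks the vial through the inoculation plan (PBS first, then stock
    additions), taking ``reads_per_point`` consecutive raw reads per step
    (median recorded, as on hardware).  ``stock_od_actual`` is the true stock
    OD; when it differs from the plan's nominal value, the true per-point ODs
    differ from the nominal ones exactly as a mis-measured stock would make
    them — the error the back-calculation step exists to remove.

    Returns ``(dataset, measured_final_od)`` where the endpoint OD carries
    optional spectrophotometer noise ``spectro_sd``.
    """
    from .calibration import CalibrationDataset, CalibrationPoint

    rng = _as_rng(rng)
    if stock_od_actual is None:
        stock_od_actual = plan.stock_od_nominal
    points = []
    for step in plan.steps:
        od_true = stock_od_actual * step.cumulative_fraction
        culture = None if od_true == 0 else TrueCulture(od_true=od_true)
        reads = np.array(
            [
                measure_raw(optics, vial, culture, rng, noise=noise)
                for _ in range(reads_per_point)
            ]
        )
        points.append(
            CalibrationPoint(
                raw_mean=float(np.median(reads)),
                raw_sd=float(reads.std(ddof=1)) if reads_per_point > 1 else 0.0,
                nominal_od=step.nominal_od,
            )
        )
    measured_final = stock_od_actual * plan.final_fraction
    if spectro_sd > 0:
        measured_final += float(rng.normal(0.0, spectro_sd))
    dataset = CalibrationDataset(
        sleeve_id=optics.sleeve_id,
        vial_id=vial.vial_id,
        led_power=optics.led_power,
        points=points,
    )
    return dataset, measured_final


# ---------------------------------------------------------------------------
# Scenario configuration


@dataclass
class Scenario:
    """Replayable description of one simulated sleeve/vial/culture setup."""

    seed: int = 0
    cadence_s: float = DEFAULT_CADENCE_S
    sleeve_id: str = "S0"
    led_power: int = 2
    noise_sd: float = DEFAULT_NOISE_SD
    vial_id: str = "V0"
    glass_offset: float | None = None  # None: drawn from the offset distribution
    rotation_sd: float = DEFAULT_ROTATION_SD
    volume_ml: float = 25.0
    od_start: float = 0.35
    doubling_time_h: float = 2.5
    stress_factor: float = 1.0

    def build(self, rng=None) -> tuple[TrueOptics, TrueVial, TrueCulture]:
        rng = _as_rng(self.seed if rng is None else rng)
        optics = make_optics(self.sleeve_id, self.led_power, noise_sd=self.noise_sd)
        offset = self.glass_offset
        if offset is None:
            offset = float(rng.normal(0.0, DEFAULT_GLASS_OFFSET_SD))
        vial = TrueVial(
            vial_id=self.vial_id,
            glass_offset=offset,
            rotation_sd=self.rotation_sd,
            volume_ml=self.volume_ml,
        )
        culture = TrueCulture(
            od_true=self.od_start,
            doubling_time_h=self.doubling_time_h,
            stress_factor=self.stress_factor,
        )
        return optics, vial, culture

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path
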