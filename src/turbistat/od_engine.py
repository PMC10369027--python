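"""Delta-raw OD computation: glass-offset-immune optical density from raw scattering.

An experiment starts by measuring a medium-only blank ``raw_blank`` on the
same fixed vial that was calibrated.  At any later time the culture OD is

    delta_raw = raw_t - raw_blank
    od        = f(raw_0_cal + delta_raw)

where ``raw_0_cal`` is the raw value of the PBS anchor point of the
calibration and f the calibration curve.  Because both raw_t and raw_blank
are read through the same glass, any additive vial offset cancels exactly in
delta_raw — the property that makes readings survive small vial movements and,
with a blank reset, full vial swaps.  The legacy path
``f(raw_t) - f(raw_blank)`` is kept for comparison: it only matches where f
is linear and degrades with the glass offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np

from .calibration import CalibrationCurve

__all__ = [
    "BlankRecord",
    "ODReading",
    "record_blank",
    "compute_od",
    "legacy_od",
    "blank_consistency_check",
    "append_od_reading",
    "read_od_log",
]

#: Maximum peak-to-peak spread (raw units) tolerated across blank reads;
#: larger spreads suggest the vial moved between reads.
DEFAULT_DISPERSION_GATE = 300.0
#: ODs below this are flagged as suspicious rather than clamped.
NEGATIVE_OD_FLAG = -0.02


@dataclass(frozen=True)
class BlankRecord:
    """Medium-only reference read of one vial at experiment start."""

    vial_id: str
    raw_blank: float
    dispersion: float
    n_reads: int
    od_blank: float | None = None  # legacy-path intermediate, kept for comparison
    timestamp: datetime | None = None


@dataclass(frozen=True)
class ODReading:
    vial_id: str
    raw_t: float
    delta_raw: float
    od: float
    timestamp: datetime | None = None
    extrapolated: bool = False
    flagged_negative: bool = False


def record_blank(
    vial_id: str,
    raws,
    *,
    curve: CalibrationCurve | None = None,
    dispersion_gate: float = DEFAULT_DISPERSION_GATE,
    timestamp: datetime | None = None,
) -> BlankRecord:
    """Median of repeated medium-only reads, gated on their spread.

    A spread above the gate usually means the vial was disturbed between
    reads; the blank is refused so the user can re-seat the vial and retry.
    """
    raws = np.asarray(list(raws), dtype=float)
    if raws.size == 0:
        raise ValueError("no blank reads supplied")
    if raws.size == 1:
        warnings.warn(
            "blank recorded from a single read; prefer >= 3 reads", stacklevel=2
        )
    dispersion = float(raws.max() - raws.min())
    if dispersion > dispersion_gate:
        raise ValueError(
            f"blank reads spread over {dispersion:.0f} raw units "
            f"(gate {dispersion_gate:.0f}); re-seat the vial and re-measure"
        )
    raw_blank = float(np.median(raws))
    od_blank = None
    if curve is not None:
        od_blank = curve.od_from_raw(raw_blank)
    return BlankRecord(
        vial_id=vial_id,
        raw_blank=raw_blank,
        dispersion=dispersion,
        n_reads=int(raws.size),
        od_blank=od_blank,
        timestamp=timestamp,
    )


def compute_od(
    raw_t: float,
    blank: BlankRecord,
    curve: CalibrationCurve,
    *,
    timestamp: datetime | None = None,
) -> ODReading:
    """Culture OD via the delta-raw method: od = f(raw_0_cal + raw_t - raw_blank).

    Readings transposed outside the calibrated raw span are computed anyway
    but flagged as extrapolated; readings outside the curve's invertible
    domain are a hard error.  Slightly negative ODs are reported (noise is
    shown honestly), flagged below -0.02.
    """
    if blank.vial_id != curve.vial_id:
        raise ValueError(
            f"blank is for vial {blank.vial_id!r} but curve for {curve.vial_id!r}; "
            "the delta-raw method requires the calibrated vial"
        )
    delta_raw = raw_t - blank.raw_blank
    raw_final = curve.raw_0_cal + delta_raw
    lo, hi = curve.hard_raw_limits()
    if not (lo < raw_final < hi):
        raise ValueError(
            f"transposed raw value {raw_final:.0f} outside the curve's "
            f"invertible range ({lo:.0f}, {hi:.0f})"
        )
    od = curve.od_from_raw(raw_final)
    return ODReading(
        vial_id=blank.vial_id,
        raw_t=float(raw_t),
        delta_raw=float(delta_raw),
        od=float(od),
        timestamp=timestamp,
        extrapolated=not curve.in_valid_range(raw_final),
        flagged_negative=od < NEGATIVE_OD_FLAG,
    )


def legacy_od(raw_t: float, blank: BlankRecord, curve: CalibrationCurve) -> float:
    """Legacy OD path: f(raw_t) - f(raw_blank).

    Both terms run the raw values through the curved part of f at the
    glass-offset-shifted operating point, so the result inherits the offset;
    retained only for comparison studies.
    """
    return curve.od_from_raw(raw_t) - curve.od_from_raw(blank.raw_blank)


def blank_consistency_check(
    blank: BlankRecord,
    curve: CalibrationCurve,
    *,
    limit: float = 3.0 * DEFAULT_DISPERSION_GATE,
) -> bool:
    """Startup gate: medium blank should sit near the PBS anchor.

    The allowance covers the vial's glass offset plus the (noise-level)
    PBS-vs-medium scattering difference; a larger gap suggests the wrong
    vial, medium, or calibration is in use.
    """
    return abs(blank.raw_blank - curve.raw_0_cal) < limit


# ---------------------------------------------------------------------------
# Append-only per-vial OD logs (one delimited text file per vial)

_LOG_HEADER = "timestamp\traw\tdelta_raw\tod\n"


def append_od_reading(path: str | Path, reading: ODReading) -> None:
    path = Path(path)
    line = "{}\t{:.1f}\t{:.1f}\t{:.5f}\n".format(
        reading.timestamp.isoformat() if reading.timestamp else "",
        reading.raw_t,
        reading.delta_raw,
        reading.od,
    )
    if not path.exists():
        path.write_text(_LOG_HEADER + line)
    else:
        with path.open("a") as fh:
            fh.write(line)


def read_od_log(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
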