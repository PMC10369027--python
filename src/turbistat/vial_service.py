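"""Mid-experiment vial replacement: equilibrate a fresh vial or reset the blank.

Swapping a failed vial for a new one changes the glass and therefore shifts
every raw reading by a new additive offset; calibration curves for one sleeve
acquired with different vials are parallel, differing only by that raw
offset.  Two remedies, in order:

1. *Equilibrate*: rotate the new medium-filled vial until the OD displayed
   against the old medium blank is close enough to zero, then resume.
2. *Blank reset*: if no rotation gets close enough, re-measure the medium
   blank on the new vial.  The delta-raw formula then absorbs the offset
   change exactly; the calibration curve itself is never refit mid-run.

Both paths leave every other vial untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Literal

from .calibration import CalibrationCurve
from .od_engine import DEFAULT_DISPERSION_GATE, BlankRecord, record_blank

__all__ = [
    "ReplacementSession",
    "equilibrate_monitor",
    "reset_blank",
    "add_vial_midrun",
    "append_audit",
    "DEFAULT_EQUILIBRATION_GATE",
]

#: Auto-accept gate on |OD| during equilibration; what counts as
#: "non-significant for the assay" is the user's call, this is the default.
DEFAULT_EQUILIBRATION_GATE = 0.01


@dataclass
class ReplacementSession:
    """Audit record of one vial-replacement intervention."""

    vial_id: str
    raw_blank_old: float
    decision: Literal["pending", "equilibrated", "blank_reset"] = "pending"
    displayed_ods: list[float] = field(default_factory=list)
    raw_blank_new: float | None = None
    timestamp: datetime | None = None
    note: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "vial_id": self.vial_id,
                "raw_blank_old": self.raw_blank_old,
                "decision": self.decision,
                "n_reads": len(self.displayed_ods),
                "final_od": self.displayed_ods[-1] if self.displayed_ods else None,
                "raw_blank_new": self.raw_blank_new,
                "timestamp": self.timestamp.isoformat() if self.timestamp else None,
                "note": self.note,
            }
        )


def equilibrate_monitor(
    raw_stream: Iterable[float],
    blank_old: BlankRecord,
    curve: CalibrationCurve,
    *,
    gate: float = DEFAULT_EQUILIBRATION_GATE,
    max_reads: int = 500,
    display: Callable[[float], None] | None = None,
) -> ReplacementSession:
    """Live OD display for a new medium-only vial, judged against the old blank.

    Each raw read is shown as f(raw_0_cal + raw - raw_blank_old) — the OD the
    running experiment would report, which is what must come back to zero
    (the stock application's own display uses the calibration blank instead
    and cannot be trusted here).  The session ends ``equilibrated`` as soon
    as |OD| drops below the gate; if the stream is exhausted first it stays
    ``pending`` and a blank reset is the next step.
    """
    session = ReplacementSession(
        vial_id=blank_old.vial_id,
        raw_blank_old=blank_old.raw_blank,
        timestamp=datetime.now(timezone.utc),
    )
    n = 0
    for raw in raw_stream:
        od = curve.od_from_raw(curve.raw_0_cal + raw - blank_old.raw_blank)
        session.displayed_ods.append(od)
        if display is not None:
            display(od)
        if abs(od) < gate:
            session.decision = "equilibrated"
            session.note = f"|OD| {abs(od):.4f} < gate {gate} after {n + 1} reads"
            return session
        n += 1
        if n >= max_reads:
            break
    if not session.displayed_ods:
        raise TimeoutError("no reads received from the vial")
    session.note = (
        f"no orientation reached |OD| < {gate} in {len(session.displayed_ods)} "
        "reads; blank reset required"
    )
    return session


def reset_blank(
    session: ReplacementSession,
    raws_new_medium: Iterable[float],
    *,
    dispersion_gate: float = DEFAULT_DISPERSION_GATE,
) -> BlankRecord:
    """Re-anchor the delta-raw scale on the new vial's medium blank.

    Only the blank moves; the calibration curve is untouched, because a vial
    change shifts the raw scale by a constant that delta-raw cancels.  All
    subsequent OD readings for this vial use the new blank.
    """
    if session.decision == "equilibrated":
        raise ValueError("session already closed as equilibrated; no reset needed")
    if session.decision == "blank_reset":
        raise ValueError("blank already reset in this session")
    blank = record_blank(
        session.vial_id,
        raws_new_medium,
        dispersion_gate=dispersion_gate,
        timestamp=datetime.now(timezone.utc),
    )
    session.decision = "blank_reset"
    session.raw_blank_new = blank.raw_blank
    session.note += (
        f" blank moved {blank.raw_blank - session.raw_blank_old:+.0f} raw units"
    )
    return blank


def add_vial_midrun(
    vial_id: str,
    calibrated_positions: Iterable[str],
    active_positions: Iterable[str],
) -> None:
    """Validate bringing a new position online during a running assay.

    A position may only join mid-run if it was calibrated before the
    experiment started (its stored curve and anchor exist) and is not already
    active; it then goes through the standard replacement workflow before the
    controller loop attaches.
    """
    if vial_id not in set(calibrated_positions):
        raise ValueError(
            f"position {vial_id!r} has no pre-experiment calibration; "
            "calibrate every candidate position before the assay starts"
        )
    if vial_id in set(active_positions):
        raise ValueError(f"position {vial_id!r} is already active")


def append_audit(path: str | Path, session: ReplacementSession) -> None:
    """Append one session to a JSON-lines audit log."""
    with Path(path).open("a") as fh:
        fh.write(session.to_json() + "\n")
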