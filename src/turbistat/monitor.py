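"""Media accounting and surveillance: bottle ledger, scale-based consumption
forecasting, and edge-triggered alert conditions behind a pluggable notifier.

Long assays live or die on logistics: every vial must stay connected to a
bottle with medium in it, pauses must not silently stretch into hours, and a
failed dilution or power cut must reach the user.  The hardware-side
messaging services are deliberately abstracted to a notifier interface
(stdout, file, or any callable) so the conditions themselves are testable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Bottle",
    "BottleLedger",
    "ScaleSeries",
    "forecast_empty",
    "AlertEvent",
    "Notifier",
    "StdoutNotifier",
    "FileNotifier",
    "CollectingNotifier",
    "SystemState",
    "AlertMonitor",
    "PAUSE_LIMIT",
]

logger = logging.getLogger(__name__)

#: An experiment paused longer than this raises an alert (cells would grow to
#: saturation if the user forgot to resume).
PAUSE_LIMIT = timedelta(minutes=10)


# ---------------------------------------------------------------------------
# Bottle ledger


@dataclass(frozen=True)
class Bottle:
    bottle_id: str
    medium: str = ""
    start_weight_g: float = 1000.0
    density_g_per_ml: float = 1.0  # per-medium override of the water-like default
    low_limit_g: float = 100.0


class BottleLedger:
    """Assignments of vials to media bottles plus the full consumption history.

    Every vial draws from exactly one bottle at any time; a bottle switch
    re-points a set of vials and is logged.  Consumption events come from the
    controller's dilution events, so ledger totals reconcile exactly with
    commanded medium.
    """

    def __init__(self):
        self.bottles: dict[str, Bottle] = {}
        self.assignments: dict[str, str] = {}  # vial -> bottle
        self.events: list[dict] = []
        self.switch_log: list[dict] = []

    def add_bottle(self, bottle: Bottle) -> None:
        if bottle.bottle_id in self.bottles:
            raise KeyError(f"bottle {bottle.bottle_id!r} already registered")
        self.bottles[bottle.bottle_id] = bottle

    def assign(self, vial_id: str, bottle_id: str) -> None:
        if bottle_id not in self.bottles:
            raise KeyError(f"unknown bottle {bottle_id!r}")
        self.assignments[vial_id] = bottle_id

    def switch_bottle(
        self, old_id: str, new_id: str, timestamp: datetime | None = None
    ) -> None:
        """Re-point every vial on ``old_id`` to ``new_id`` and log the switch."""
        if new_id not in self.bottles:
            raise KeyError(f"unknown bottle {new_id!r}")
        moved = [v for v, b in self.assignments.items() if b == old_id]
        if not moved:
            raise ValueError(f"no vials assigned to bottle {old_id!r}")
        for v in moved:
            self.assignments[v] = new_id
        self.switch_log.append(
            {
                "old": old_id,
                "new": new_id,
                "vials": moved,
                "timestamp": timestamp.isoformat() if timestamp else None,
            }
        )

    def record_consumption(self, event, timestamp: datetime | None = None) -> None:
        """Append one dilution's commanded volume to the assigned bottle.

        ``event`` is a controller DilutionEvent or anything with
        ``vial_id`` and ``commanded_volume_ml``.
        """
        vial_id = event.vial_id
        if vial_id not in self.assignments:
            raise KeyError(f"vial {vial_id!r} is not assigned to any bottle")
        self.events.append(
            {
                "vial_id": vial_id,
                "bottle_id": self.assignments[vial_id],
                "volume_ml": float(event.commanded_volume_ml),
                "timestamp": timestamp.isoformat() if timestamp else None,
            }
        )

    def per_vial_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.events:
            out[e["vial_id"]] = out.get(e["vial_id"], 0.0) + e["volume_ml"]
        return out

    def per_bottle_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.events:
            out[e["bottle_id"]] = out.get(e["bottle_id"], 0.0) + e["volume_ml"]
        return out

    def total_consumed_ml(self) -> float:
        return sum(e["volume_ml"] for e in self.events)

    # JSON-lines persistence -------------------------------------------------

    def dump_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            for b in self.bottles.values():
                fh.write(json.dumps({"kind": "bottle", **b.__dict__}) + "\n")
            for v, b in self.assignments.items():
                fh.write(
                    json.dumps({"kind": "assignment", "vial_id": v, "bottle_id": b})
                    + "\n"
                )
            for e in self.events:
                fh.write(json.dumps({"kind": "consumption", **e}) + "\n")
            for s in self.switch_log:
                fh.write(json.dumps({"kind": "switch", **s}) + "\n")
        return path

    @classmethod
    def load_jsonl(cls, path: str | Path) -> "BottleLedger":
        ledger = cls()
        for line in Path(path).read_text().splitlines():
            rec = json.loads(line)
            kind = rec.pop("kind")
            if kind == "bottle":
                ledger.bottles[rec["bottle_id"]] = Bottle(**rec)
            elif kind == "assignment":
                ledger.assignments[rec["vial_id"]] = rec["bottle_id"]
            elif kind == "consumption":
                ledger.events.append(rec)
            elif kind == "switch":
                ledger.switch_log.append(rec)
        return ledger


# ---------------------------------------------------------------------------
# Scale series and consumption forecasting


@dataclass
class ScaleSeries:
    """Weight-over-time samples from the scale under one bottle."""

    bottle_id: str
    samples: list[tuple[float, float]] = field(default_factory=list)  # (t_h, weight_g)
    low_limit_g: float = 100.0

    def add_sample(self, t_h: float, weight_g: float) -> None:
        if self.samples and t_h <= self.samples[-1][0]:
            raise ValueError("scale timestamps must be strictly increasing")
        self.samples.append((float(t_h), float(weight_g)))


def forecast_empty(
    series: ScaleSeries,
    density_g_per_ml: float = 1.0,
    *,
    window_h: float = 6.0,
) -> tuple[float, float]:
    """Consumption rate and time until the bottle needs changing.

    Fits weight vs time over the trailing ``window_h`` hours with a
    Theil-Sen line (robust to the spikes a nudged scale produces), then
    extrapolates to the low limit:

        rate = -slope / density      [mL/h]
        eta  = (weight_now - low_limit) / -slope   [h]

    A flat or rising weight gives zero rate and an infinite eta.
    """
    if len(series.samples) < 2:
        raise ValueError("need at least 2 scale samples to forecast")
    t = np.array([s[0] for s in series.samples])
    w = np.array([s[1] for s in series.samples])
    recent = t >= t[-1] - window_h
    if recent.sum() < 2:  # sparse logging: fall back to the last two samples
        recent = np.zeros_like(recent)
        recent[-2:] = True
    t, w = t[recent], w[recent]
    if np.allclose(w, w[0]):
        slope = 0.0
    else:
        slope = float(stats.theilslopes(w, t)[0])  # g/h
    if slope >= 0:
        return 0.0, math.inf
    rate_ml_per_h = -slope / density_g_per_ml
    eta_h = (float(w[-1]) - series.low_limit_g) / -slope
    return rate_ml_per_h, max(eta_h, 0.0)


def series_from_ledger(
    ledger: BottleLedger,
    bottle_id: str,
    event_times_h: Sequence[float],
    *,
    low_limit_g: float | None = None,
) -> ScaleSeries:
    """Synthetic scale trace implied by the ledger's consumption history."""
    bottle = ledger.bottles[bottle_id]
    series = ScaleSeries(
        bottle_id=bottle_id,
        low_limit_g=bottle.low_limit_g if low_limit_g is None else low_limit_g,
    )
    weight = bottle.start_weight_g
    events = [e for e in ledger.events if e["bottle_id"] == bottle_id]
    if len(events) != len(event_times_h):
        raise ValueError("one timestamp per consumption event required")
    series.add_sample(0.0, weight)
    for e, t in zip(events, event_times_h):
        weight -= e["volume_ml"] * bottle.density_g_per_ml
        series.add_sample(t, weight)
    return series


# ---------------------------------------------------------------------------
# Alerts


@dataclass(frozen=True)
class AlertEvent:
    kind: str  # code_error | paused_too_long | low_medium | power_loss | dilution_failure
    payload: Mapping
    timestamp: datetime


class Notifier(Protocol):
    def notify(self, event: AlertEvent) -> None: ...


class StdoutNotifier:
    def notify(self, event: AlertEvent) -> None:
        print(f"[{event.timestamp.isoformat()}] ALERT {event.kind}: {dict(event.payload)}")


class FileNotifier:
    """JSON-lines alert log."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def notify(self, event: AlertEvent) -> None:
        with self.path.open("a") as fh:
            fh.write(
                json.dumps(
                    {
                        "timestamp": event.timestamp.isoformat(),
                        "kind": event.kind,
                        "payload": dict(event.payload),
                    }
                )
                + "\n"
            )


class CollectingNotifier:
    """In-memory sink, mainly for tests and composition."""

    def __init__(self):
        self.events: list[AlertEvent] = []

    def notify(self, event: AlertEvent) -> None:
        self.events.append(event)


@dataclass
class SystemState:
    """Snapshot of everything the surveillance rules look at."""

    paused_since: datetime | None = None
    code_error: str | None = None
    scale_weights: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )  # bottle -> (weight_g, low_limit_g)
    last_scale_heartbeat: datetime | None = None
    dilution_failures: list = field(default_factory=list)  # drained on check


class AlertMonitor:
    """Edge-triggered surveillance: each condition fires once per episode.

    An episode opens when its condition first holds and closes when it stops
    holding; re-checks inside an open episode do not re-notify.  Notifier
    failures are logged and never propagate into the control loop.
    """

    def __init__(
        self,
        notifier: Notifier | None = None,
        *,
        pause_limit: timedelta = PAUSE_LIMIT,
        heartbeat_timeout: timedelta = timedelta(minutes=5),
    ):
        self.notifier = notifier
        self.pause_limit = pause_limit
        self.heartbeat_timeout = heartbeat_timeout
        self._active: set[tuple] = set()

    def _emit(self, events: list[AlertEvent], key: tuple, kind: str, payload: Mapping, now):
        if key not in self._active:
            self._active.add(key)
            events.append(AlertEvent(kind=kind, payload=payload, timestamp=now))

    def _clear(self, key: tuple):
        self._active.discard(key)

    def check(self, state: SystemState, now: datetime) -> list[AlertEvent]:
        events: list[AlertEvent] = []

        key = ("paused_too_long",)
        if state.paused_since is not None and now - state.paused_since > self.pause_limit:
            minutes = (now - state.paused_since).total_seconds() / 60.0
            self._emit(
                events, key, "paused_too_long", {"paused_min": round(minutes, 1)}, now
            )
        else:
            self._clear(key)

        key = ("code_error",)
        if state.code_error:
            self._emit(events, key, "code_error", {"error": state.code_error}, now)
        else:
            self._clear(key)

        for bottle_id, (weight, low_limit) in state.scale_weights.items():
            key = ("low_medium", bottle_id)
            if weight < low_limit:
                self._emit(
                    events,
                    key,
                    "low_medium",
                    {"bottle_id": bottle_id, "weight_g": weight, "low_limit_g": low_limit},
                    now,
                )
            else:
                self._clear(key)

        key = ("power_loss",)
        heartbeat_missing = state.last_scale_heartbeat is None or (
            now - state.last_scale_heartbeat > self.heartbeat_timeout
        )
        if state.scale_weights and heartbeat_missing:
            self._emit(
                events,
                key,
                "power_loss",
                {
                    "last_heartbeat": state.last_scale_heartbeat.isoformat()
                    if state.last_scale_heartbeat
                    else None
                },
                now,
            )
        else:
            self._clear(key)

        while state.dilution_failures:
            ev = state.dilution_failures.pop(0)
            events.append(
                AlertEvent(
                    kind="dilution_failure",
                    payload={
                        "vial_id": ev.vial_id,
                        "rounds": ev.rounds,
                        "od_after": ev.od_after,
                    },
                    timestamp=now,
                )
            )

        for event in events:
            if self.notifier is not None:
                try:
                    self.notifier.notify(event)
                except Exception:
                    logger.exception("notifier failed for %s", event.kind)
        return events


def consumption_report(
    ledger: BottleLedger,
    scale_series: Mapping[str, ScaleSeries] | None = None,
) -> str:
    """Plain-text per-vial/per-bottle consumption and bottle-change forecast."""
    lines = ["per-vial consumption (mL):"]
    for vial, total in sorted(ledger.per_vial_totals().items()):
        lines.append(f"  {vial:>8s}  {total:10.1f}")
    lines.append("per-bottle consumption (mL):")
    for bottle, total in sorted(ledger.per_bottle_totals().items()):
        lines.append(f"  {bottle:>8s}  {total:10.1f}")
    if scale_series:
        lines.append("bottle forecasts:")
        for bottle_id, series in sorted(scale_series.items()):
            bottle = ledger.bottles.get(bottle_id)
            density = bottle.density_g_per_ml if bottle else 1.0
            rate, eta = forecast_empty(series, density)
            eta_txt = "inf" if math.isinf(eta) else f"{eta:8.1f} h"
            lines.append(f"  {bottle_id:>8s}  {rate:8.2f} mL/h   change in {eta_txt}")
    return "\n".join(lines)
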