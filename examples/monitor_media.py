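"""Media accounting and surveillance for a two-bottle assay.

Builds a bottle ledger, replays some consumption, forecasts when each bottle
needs changing from a synthetic scale trace, checks the media-equivalence
report that justifies calibrating in PBS, and walks the alert monitor through
a pause that overruns the 10-minute rule.
"""

from datetime import datetime, timedelta
from types import SimpleNamespace

from turbistat.calibration import media_equivalence_report
from turbistat.monitor import (
    AlertMonitor,
    Bottle,
    BottleLedger,
    CollectingNotifier,
    SystemState,
    consumption_report,
    series_from_ledger,
)

ledger = BottleLedger()
ledger.add_bottle(Bottle("B-EMM", medium="EMM", start_weight_g=2000.0))
ledger.add_bottle(Bottle("B-YE4S", medium="YE4S", start_weight_g=2000.0))
for vial, bottle in [("V0", "B-EMM"), ("V1", "B-EMM"), ("V2", "B-YE4S")]:
    ledger.assign(vial, bottle)

event_times = {"B-EMM": [], "B-YE4S": []}
for i in range(10):
    t_round = 1.8 * (i + 1)
    for j, vial in enumerate(("V0", "V1", "V2")):
        ledger.record_consumption(
            SimpleNamespace(vial_id=vial, commanded_volume_ml=14.8)
        )
        event_times[ledger.assignments[vial]].append(t_round + 0.01 * j)

series = {
    b: series_from_ledger(ledger, b, ts) for b, ts in event_times.items()
}
print(consumption_report(ledger, series))

print("\nmedia scattering vs water (raw units):")
print(media_equivalence_report()[["raw_mean", "raw_sd", "diff_raw"]])

sink = CollectingNotifier()
monitor = AlertMonitor(sink)
t0 = datetime(2026, 2, 1, 9, 0)
state = SystemState(paused_since=t0)
for minutes in (5, 9, 12, 20):
    monitor.check(state, t0 + timedelta(minutes=minutes))
print(f"\npause alerts fired: {[e.kind for e in sink.events]} "
      "(once, despite four checks past the limit)")
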