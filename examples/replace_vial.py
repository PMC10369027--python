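"""Cure the OD error a mid-experiment vial swap introduces.

A replacement glass vial shifts every raw reading by a new additive offset.
Reading the culture against the old medium blank then reports a wrong OD;
resetting the blank on the new vial (medium only) restores accuracy without
touching the calibration curve — the delta-raw formula absorbs the offset.
"""

import numpy as np

from turbistat import virtualrig as vr
from turbistat.protocols import calibrate_position, measure_blank, vial_swap_study
from turbistat.vial_service import equilibrate_monitor

result = vial_swap_study(seed=1, offset_shift=500.0, od_true=0.35)
print("vial swapped: new glass offset +500 raw units, true culture OD 0.35")
print(f"  OD against the stale blank : {result['od_stale_blank']:.4f} "
      f"(error {result['error_stale']:.4f})")
print(f"  OD after blank reset       : {result['od_after_reset']:.4f} "
      f"(error {result['error_after_reset']:.4f})")
print(f"  session decision           : {result['session'].decision}")

# the gentler path: rotate the new medium-filled vial until the displayed OD
# zeroes against the old blank (no reset needed if an orientation matches)
rng = np.random.default_rng(3)
optics = vr.make_optics("S0", 2)
old = vr.TrueVial("V0", glass_offset=100.0)
curve = calibrate_position(optics, old, rng=rng)
blank_old = measure_blank(optics, old, rng=rng)
new = vr.swap_vial(old, new_offset=450.0, new_id="V0")


def rotating_reads():
    vial = new
    for _ in range(300):
        yield vr.measure_raw(optics, vial, None, rng)
        vial = vr.rotate(vial, rng)


session = equilibrate_monitor(rotating_reads(), blank_old, curve, gate=0.01)
print(f"equilibration by rotation    : {session.decision} "
      f"after {len(session.displayed_ods)} reads "
      f"(final displayed OD {session.displayed_ods[-1]:+.4f})")
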