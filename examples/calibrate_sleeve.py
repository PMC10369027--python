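"""Calibrate one sleeve position with the fixed-vial protocol.

Plans the inoculation ladder, simulates the measurements on the virtual rig
with a deliberately mis-estimated stock OD, back-calculates the true stock
from the endpoint spectrophotometer read, fits the monotone curve, and picks
the best LED power.  The point of the printout: the back-calculation recovers
the actual stock OD, and the fitted curve inverts the rig's true optics to
well under 0.01 OD across the working range.
"""

import numpy as np

from turbistat import virtualrig as vr
from turbistat.calibration import (
    backcalculate_stock,
    correct_calibration,
    default_target_ods,
    fit_curve,
    plan_inoculation,
    plan_temp_calibration,
    select_led_power,
)
from turbistat.protocols import calibrate_position

optics = vr.make_optics("sleeve-3", led_power=2)
vial = vr.TrueVial("vial-3", glass_offset=180.0)
rng = np.random.default_rng(42)

# the stock was *believed* to be OD 20 but is actually OD 20.8
plan = plan_inoculation(default_target_ods(10, 0.8), vial.volume_ml, 20.0)
dataset, endpoint_od = vr.simulate_calibration_run(
    optics, vial, plan, stock_od_actual=20.8, rng=rng
)
stock_actual, corrected = backcalculate_stock(plan, [endpoint_od])
dataset = correct_calibration(dataset, corrected)
curve = fit_curve(dataset)

print(f"endpoint spectrophotometer OD : {endpoint_od:.4f}")
print(f"back-calculated stock OD      : {stock_actual:.3f}  (true 20.8)")
print(f"PBS anchor raw_0_cal          : {curve.raw_0_cal:.0f}")
print(f"fit residual (raw units RMSE) : {curve.rmse_raw:.1f}")

errs = [
    abs(curve.od_from_raw(float(optics.g(od)) + vial.glass_offset) - od)
    for od in np.linspace(0.0, 0.8, 100)
]
print(f"max |fitted - true| over [0, 0.8] OD : {max(errs):.4f}")

# LED selection: fit one curve per candidate power, keep the steepest window
curves = {
    p: calibrate_position(vr.make_optics("sleeve-3", p), vial, rng=rng)
    for p in (1, 2, 3)
}
print(f"selected LED power            : {select_led_power(curves)} (of 1/2/3)")

plan_t = plan_temp_calibration(room_temp_c=22.0, offset_c=0.15)
print(f"temperature setpoints (C)     : {plan_t.setpoints_c}")
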