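# turbistat

Calibration and control software for long-term continuous-culture
(turbidostat) evolution rigs of the smart-sleeve type: multiplexed vials,
each with an LED/photodiode pair that reports culture density as a raw
light-scattering value, an influx/efflux pump pair, and a heater.  The
package is aimed at labs running laboratory-evolution assays for weeks to
months, where small optical biases — a vial rotated a few degrees, a swapped
glass vial, a flat calibration curve — accumulate into wrong growth rates and
unstable density control.

Everything is validated against a bundled **virtual rig** (`virtualrig`)
that emulates the measurement phenomenology — monotone saturating optics,
additive per-glass-vial offsets, read noise, exponential growth, bolus
dilution — so the whole stack runs and is tested without hardware.

## What it computes

**Fixed-vial calibration** (`calibration`).  Each sleeve is calibrated with a
single fixed glass vial: a PBS-only anchor read `raw_0_cal`, then successive
inoculations from a concentrated stock step the vial through increasing ODs.
Because the stock's own OD is hard to measure, it is back-calculated from an
endpoint spectrophotometer reading and the cumulative dilution fraction
(`stock = OD_end / fraction_end`), and every calibration OD is rescaled
before fitting.  The curve family is a 4-parameter monotone logistic

    raw = a + b / (1 + exp((OD − c) / d)),

fitted by least squares with deterministic initialisation; OD lookup uses its
analytic inverse.  The module also selects the LED power that maximises the
worst-case |d raw/d OD| over the working window (OD 0.2–0.5), plans the
three-point temperature calibration (RT, RT+6, RT+12 °C), and manages a
calibration store.

**Δraw OD engine** (`od_engine`).  During an assay the OD is not computed
from the raw reading directly but from the *difference* to the experiment's
medium blank, transposed onto the calibration anchor:

    Δraw = raw_t − raw_blank,    OD = f(raw_0_cal + Δraw).

Both reads go through the same glass, so any additive vial offset cancels
exactly — the property that makes readings immune to vial movement.  The
legacy path `f(raw_t) − f(raw_blank)` is kept for comparison; it degrades
with the glass offset wherever the curve bends.

**Turbidostat controller** (`controller`).  Dilute when OD ≥ HT, inject
medium until OD ≤ LT (bolus volume `V·(OD/LT − 1)`, capped per round),
count the rounds needed as a pump-health diagnostic, and estimate the growth
rate by OLS on ln(OD) vs time between successive dilutions, smoothed over a
sliding window of 10 estimates (doubling time = ln 2 / μ).

**Vial replacement** (`vial_service`) restarts a failed position mid-assay:
rotate the new medium-filled vial until the displayed OD zeroes against the
old blank, or reset the blank on the new vial — the curve is never refit.

**Monitoring** (`monitor`): bottle/vial assignment ledger with exact
consumption accounting, scale-based consumption-rate and bottle-change
forecasting (Theil–Sen), and edge-triggered alerts (pause > 10 min, low
medium, power loss, dilution failure) behind a pluggable notifier.

## Worked example

```bash
python examples/run_turbidostat.py
```

```
samples                 : 5291 (16-s cadence)
dilution events         : 13
rounds per dilution     : [2]
OD in [0.25, 0.55]      : 100.00% of samples
cycle period            : 1.84 h (theory 1.84 h)
doubling time estimates : 2.481 h mean over 14 segments (true 2.5 h)
smoothed growth rate    : 0.2796 /h (last window mean)
medium commanded        : 191.7 mL
ledger total            : 191.7 mL
ledger reconciles       : True
```

A 24-hour closed loop holds the culture inside the density band on every
sample; the cycle period matches the theoretical
`doubling_time · log2(HT/LT)`; the growth fits recover the simulated 2.5 h
doubling time; and the media ledger reconciles exactly with commanded
volumes.  `examples/calibrate_sleeve.py` (calibration + LED selection +
temperature plan), `examples/replace_vial.py` (swap-cure) and
`examples/monitor_media.py` (ledger, forecast, alerts) narrate the other
capabilities.  A thin CLI mirrors the library
(`turbistat calibrate ... | run | replace-vial | report`).

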