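# Methods

## Measurement model

A smart sleeve reports culture density as a raw light-scattering value
(arbitrary units, ~4×10⁴ scale).  The package models the raw signal of one
sleeve as

    raw = g(OD) + offset_vial + ε,     ε ~ N(0, σ_read²)

where `g` is a strictly monotone saturating map, `offset_vial` is an additive
constant set by the particular glass vial and its orientation, and `σ_read`
is the shot-to-shot read noise.  Three empirical facts shape everything
downstream:

1. **The glass term is additive and large.**  Curves calibrated on the same
   sleeve with different vials are parallel, differing by a constant raw
   offset; rotating a vial a few degrees re-draws that offset with a spread
   well above read noise.
2. **`g` bends.**  A logistic-shaped saturation means a raw offset translates
   into an OD error whose size depends on the operating point — offsets
   cannot be corrected in OD units.
3. **PBS and growth media scatter alike** (differences at the read-noise
   scale), so a PBS anchor and a medium blank can share one Δraw scale.
   `media_equivalence_report` reproduces the reference per-medium
   water-referenced differences and `check_media_equivalence` applies the
   3×σ_read rule to fresh readings.

### Virtual rig

`virtualrig` implements exactly this model as the ground truth for the test
suite, with pure exponential growth between pump events
(`OD(t+dt) = OD·2^(dt·s/T)` with doubling time `T` and stress factor
`s ∈ (0,1]`) and bolus dilution at constant vessel volume
(`OD' = OD·V/(V+v)`), i.e. an instantaneous injection with matched efflux
rather than continuous co-flow washout.  At the 16-s sampling cadence used
the two are indistinguishable at the thresholds; the bolus form makes the
controller's mass balance exact and testable.

Defaults (all configurable, all draws from one explicit generator per
scenario so every dataset replays exactly):

| parameter | default | why |
|---|---|---|
| read noise σ_read | 50 raw units | puts the SD of repeated fixed-vial reads in the 30–79 band observed on real sleeves |
| glass offset across vials | N(0, 250) raw | reproduces the vial-to-vial OD spread seen when splitting one culture across vials |
| rotation step | N(0, 250) raw | rotation re-samples the same glass-path distribution that distinguishes vials; sized so a 5-read rotated sample fails a variance test against 447 fixed reads in ≥95% of runs, as on hardware |
| optics `g` | logistic, amplitude 6000·LED power, midpoint OD 0.35, scale 0.18, floor 30600 | raw ≈ 41k at OD 0, raw decreasing in OD; worst-case slope over OD 0.2–0.5 grows strictly with LED power |
| cadence | 16 s | 447 points in 2 h |
| doubling time | 2.5 h | fission yeast in minimal medium at 32 °C |

The curve direction (raw falling with OD) is a simulator convention only;
every consumer assumes monotonicity, never sign, and the fit handles rising
data (covered by a test).

What the rig does **not** emulate: wall growth/biofilm, drift of the optics
over weeks, non-Gaussian noise bursts, fluid dynamics of the dilution
transient, and any mutation/selection dynamics — adaptation appears only as a
user-scripted time-varying stress factor.  Passing tests therefore certify
the *algorithms* (offset cancellation, back-calculation, control logic,
accounting), not robustness to every failure mode of real hardware.

## Fixed-vial calibration

One vial per sleeve, never moved: PBS anchor first (`raw_0_cal`), then a
ladder of stock inoculations.  Ten points by default, OD 0 plus nine
geometrically spaced targets to 0.8 (geometric spacing concentrates points
where the curve bends); per point the median of 5 consecutive reads is used
(median for outlier robustness).  The cumulative stock volume for target `t`
solves `S·v/(V+v) = t`, accounting for the vial volume growing with each
addition; the stock must be ≥20× the top target so the total addition stays
below ~4% of the vial volume.

**Back-calculation.**  The endpoint OD of every vial that shared a stock is
measured on a spectrophotometer and averaged (mean; distinct stocks averaged
separately); since the cumulative fraction at the end is known exactly,
`stock_actual = mean(OD_end)/fraction_end`, and all point ODs are rescaled.
This removes the stock-OD measurement error entirely (scale-consistency is a
tested property).  With the fixed-vial protocol every sleeve acquires points
in the same order, so the legacy re-ordering step (undoing a 16-vial
rotational permutation) is an explicit identity; monotonicity violations
beyond 3× the per-point read SD are flagged, not fatal.

**Fit.**  Least squares (`scipy.optimize.curve_fit`) of the 4-parameter
logistic in the raw-vs-OD direction, initialised deterministically from the
data span and quantiles (no random restarts, so refits are bit-identical);
OD lookup is the analytic inverse `od = c + d·ln(b/(raw−a) − 1)`.  Fitting
in this direction means noise-free data from logistic-shaped optics is
recovered exactly; the stored `valid_raw_range` is the calibrated raw span
±2%, outside of which readings are flagged as extrapolation (readings
outside the asymptotes are a hard error).  The anchor must map near OD 0
(warned beyond 0.02).

**LED selection** maximises the worst-case |d raw/d OD| over OD 0.2–0.5.
|g′| is unimodal, so the window minimum sits at an endpoint and is evaluated
analytically; a dense-grid numerical oracle cross-checks it in the tests.
Ties break to the lower power (less heating, longer LED life).

**Temperature.**  Three setpoints at RT, RT+6, RT+12 °C — inside the
physiological range of yeast growth and reachable by the heaters even in
warm rooms — then an OLS line from sleeve-surface temperature to a reference
probe.  A residual constant offset (cultures run ≈0.15 °C below target on
real rigs) can be folded into the commanded target (`requested + offset`).

## Δraw OD computation

`OD = f(raw_0_cal + raw_t − raw_blank)`.  The blank is the median of ≥3
medium-only reads on the experiment vial, gated on a peak-to-peak spread of
300 raw units (6× default read noise; a larger spread means the vial moved
between reads).  Negative ODs are reported, not clamped — the controller and
QC should see the noise floor honestly — and flagged below −0.02.  A startup
gate warns when `|raw_blank − raw_0_cal|` exceeds the glass-offset allowance
(wrong vial, medium or calibration).  The offset-invariance property
(`compute_od(raw_t+c, blank+c) ≡ compute_od(raw_t, blank)`) is exact: raw
values are integer ADC counts, so the cancellation holds in floating point,
and the property test draws integers accordingly.

## Controller

Trigger inclusively at HT; target LT with bolus volume `V·(OD/LT − 1)`
capped at 40% of the vessel volume per round (bounded pump actuation — large
HT/LT ratios legitimately take ≥2 rounds, and stepwise boluses are slightly
more volume-efficient than a single large one).  Rounds stop once
OD ≤ LT + 0.01 (tolerance prevents micro-dilution chatter at the noise
floor); exhausting `max_rounds` (default 5) marks the event failed and feeds
the `dilution_failure` alert.  Growth fits use OLS on ln(OD) vs time over
each inter-dilution segment, excluding readings within one settle time
(default 60 s) after a dilution to keep mixing transients out, requiring ≥5
positive-OD points; the doubling time is ln 2/μ, undefined for μ ≤ 0.  The
10-point trailing window mean smooths the estimate series.

## Vial replacement

Equilibration displays `f(raw_0_cal + raw − raw_blank_old)` live and
auto-accepts below |OD| < 0.01 by default (what is "negligible" is assay-
specific and user-set).  Otherwise the blank is re-measured on the new vial;
the curve is never refit mid-run, because a vial change moves the raw scale
by a constant that Δraw absorbs exactly — an algebraic identity tested across
an offset grid.  Sessions are audited as JSON lines; per-vial random streams
keep non-replaced vials' logs byte-identical whether or not a replacement
happened elsewhere.

## Monitoring

The ledger stores volumes exactly as commanded, so per-vial, per-bottle and
controller totals reconcile with `==`, not a tolerance.  Consumption
forecasting fits weight vs time with Theil–Sen over a trailing 6 h window
(robust to scale nudges; falls back to the last two samples when logging is
sparse), converts by per-medium density (default 1.0 g/mL), and extrapolates
to the bottle's low limit; flat or rising weight gives infinite ETA.  Alerts
are edge-triggered per episode — pause > 10 min, bottle below its limit,
scale heartbeat older than 5 min (power loss), code error, dilution failure
— and dispatched to a notifier interface (stdout/file/in-memory provided;
messaging hardware integrations are out of scope by design, pluggable).

## Problem sizes used in validation

The recovery study runs 100 independently seeded positions for 8 simulated
hours at 16-s cadence (calibration, blank and loop re-done per seed); the
soak test runs one position for 72 h; the rotation-variance check uses 200
sessions of 447 fixed + 5 rotated reads; the noisy-fit study 100
calibrations.  These sizes give Monte-Carlo standard errors comfortably
below the tolerances asserted while the whole suite stays in the ~10 s
range.

## Known limitations

Single-channel (135°) scattering only; no turbidity-to-cell-count
conversion; no chemostat or morbidostat modes; the legacy 16-vial
permutation calibration is readable but not re-implemented; long-horizon
evolutionary dynamics are represented only through the stress-factor hook.
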