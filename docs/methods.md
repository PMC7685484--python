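# Methods

This note documents the models, the parameter choices, and the places where
the design was genuinely open. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Thermistor calibration

The sensor is a negative-temperature-coefficient thermistor whose
linearized model is 1/T = A + ln(R)/B, T in Kelvin, R in kΩ, B in Kelvin.
B is estimated pairwise, B = (ln R₁ − ln R₂)/(1/T₁ − 1/T₂), and the
multi-point fit is the unweighted mean over all unordered pairs (6 pairs
for the default 4-point table), with A then averaged over points. The
pairwise mean is used instead of a least-squares line because it is the
standard bench procedure for this sensor class and weights every
temperature pair equally; on noiseless data the two coincide. The pairwise
estimator is written as a difference of logs so that swapping the arguments
negates numerator and denominator exactly, making it bit-symmetric.

All arithmetic is in Kelvin. Domain guards: resistances must be positive,
temperatures above absolute zero, and a pair at equal temperatures is
rejected as degenerate. Full three-coefficient Steinhart–Hart fitting and
sensor self-heating are out of scope; over 4–90 °C the beta model
round-trips to better than 1e-9 °C, which is far below sensor noise.
An ADC voltage-divider helper (`adc_to_resistance`) is provided for users
feeding raw microcontroller counts; the simulation path does not use it.

## Thermal plant

The heated slide assembly is one lumped thermal compartment,

    T_ss(u) = T_amb + g·u (+ optional quadratic term, default 0),
    dT/dt   = (T_ss − T)/τ,

advanced with the exact exponential update so step size never affects
accuracy (an explicit-Euler oracle is kept in the tests as an independent
check). Defaults: g = 1.28 °C/PWM-unit, fixed by the bench anchor that
full permitted drive (PWM = 50) from a 25 °C room reaches 89 °C steady
state, i.e. g = (89 − 25)/50; τ = 114 s = 1.9 min, the passive-cooling
relaxation constant; sensor read noise 0.05 °C (chosen so the closed-loop
standard deviation stays near the 0.05 °C scale, comfortably below the
0.2 °C the hardware achieves); process noise off by default. A single
compartment with symmetric heating/cooling is defensible because measured
transitions of such devices are well fit by single exponentials; the
heating asymmetry of the real Peltier stack is absorbed by the controller
tuning. There is no heatsink and hence no below-ambient capability:
"cooling" is the PWM = 0 relaxation toward ambient. Spatial gradients
across the pad are not modeled.

The simulated thermistor adds Gaussian noise to the true plate temperature
and can optionally round-trip the reading through the calibrated
resistance map (`via_calibration=True`), exercising the same code path a
physical readout would; the round trip is an identity to 1e-6 °C.

## Controller

Discrete PID at the device's 0.5-s sampling, integer PWM output (rounded
half-up, hardware-faithful), clamped to [0, 50] out of a possible 255 — the
cap that protects agarose pads from melting. The lower clamp *is* the
passive-cooling mode; no special casing is needed for downshifts.

Two structural choices matter:

* **Proportional (and derivative) on the measurement.** A textbook
  P-on-error loop cannot reproduce both observed behaviors of the tuned
  hardware at once on a first-order plant: a gentle ~0.6-min effective
  heating constant for small upshifts demands a small Kp, while settling a
  20 °C step into a ±0.3 °C band within ~2 min demands a large one. Moving
  the proportional term onto the measurement (the two-degree-of-freedom
  PID with setpoint weight b = 0, familiar as the Arduino PID library's
  "P_ON_M" mode) decouples the two: setpoint steps enter the loop only
  through the integral ramp (gentle approach, no proportional kick, no
  overshoot), while the regulation bandwidth around the setpoint keeps the
  full Kp. `PIDGains.setpoint_weight` exposes b; b = 1 recovers the
  textbook controller.
* **Conditional integration.** The integral is frozen while the output
  saturates in the direction of the error, the standard anti-windup
  device; it also preserves the integral across passive-cooling phases, so
  oscillation cycles repeat almost exactly.

Default gains Kp = 7 PWM/°C, Ki = 0.20 PWM/(°C·s), Kd = 0 are repository
constants tuned once against the plant defaults to meet the closed-loop
behaviors above, then frozen; they are configuration, not physics. Kd = 0
because derivative action on this noise level buys nothing the
P-on-measurement structure does not already provide.

Setpoint programs are piecewise-constant: hold / open-ended step /
staircase (start, increment, dwell, inclusive end) / square-wave
oscillation (high phase first, matching a heat-then-passively-cool
protocol). `run_closed_loop` iterates sense → PID → plant and logs the
*measured* temperature — what the real device records.

## Trace statistics

* `bin_trace`: tiled windows (1 min default), population sd per bin.
* `stability_stats`: mean/sd of the measured temperature after a cut-in
  time, worst |T − setpoint|, and the largest per-window sd over tiled
  3-min windows (tiled, not sliding, was chosen for the windowed variant;
  with stationary noise the two differ negligibly and tiled windows are
  independent).
* `equilibration_time`: first time after which every remaining sample is
  within the band (default ±0.3 °C — the device's error scale at its
  hottest targets; configurable). Returns `None` when the trace never
  settles.
* Time constants: a transition segment is normalized to [0, 1] using the
  mean of the minute before the shift (baseline) and of the final minute
  (plateau), then fitted with 1 − exp(−t/τ) (heating) or exp(−t/τ)
  (cooling). Amplitude and offset are fitted as nuisance parameters around
  the normalized curve: the normalization anchors them near (0, 1), but
  letting them float propagates baseline/plateau estimation noise into the
  τ confidence interval. With a fixed amplitude the nominal 95% CI covered
  the true τ in only ~31/100 noisy replicates; with nuisance parameters
  coverage is nominal (≥93/100 in the test suite) and the fitted
  passive-cooling τ equals the plant constant exactly rather than carrying
  a plateau-truncation bias. The fit is scale/offset invariant by
  construction. RMSE is reported in °C on the original scale.

## Synthetic movies

The generator emulates a temperature-shift experiment on an agarose pad as
the pipeline sees it.

**Physiology.** λ(T) is piecewise-linear through (20, 0.75), (30, 1.4),
(37, 1.98), (45, 2.0) h⁻¹. The two middle anchors are measured quantities
for fast-growing *E. coli*; the ends are plausible extensions that keep the
map monotone, and queries outside 20–45 °C clamp with a warning. After a
shift the instantaneous rate relaxes first-order toward λ(T):
τ_first = 24 min for the first shift in a direction — chosen so a
30→37 °C upshift raises the rate by ~14% in the first 10 min
(1 − e^(−10/24) ≈ 0.34 of the 0.58 h⁻¹ gap) — and τ_later = 2.5 min for
repeats, which reaches within 2% of the new steady state in 7–8 min. Shifts
are counted per direction, so the first downshift is also slow. The 30 °C
steady-state rate (1.4 h⁻¹) is itself a free parameter constrained only by
these adaptation facts. Growth follows the *measured* temperature of the
supplied trace — what the device knows — not the true plate temperature;
the difference is below sensor noise.

**Division.** Wild-type cells divide symmetrically (±3% Gaussian
imbalance) when length exceeds a per-cell threshold drawn from
N(5.0 µm, 10%); daughters inherit the phenotype and draw fresh thresholds
and rate scales (per-cell rate variability 5%). Above the nonpermissive
temperature (default 40 °C): `filamentous` cells never divide,
`rounding` cells redirect elongation into width until the aspect ratio
approaches 1, and `shrinking` cells lose projected area at 0.55 h⁻¹
(matching a ~30-min visible shrinkage at extreme heat). Width is otherwise
constant at 1.0 µm.

**Colony geometry.** Founders are scattered with a minimum spacing and
each seeds a microcolony laid out as parallel lanes of rods along the
founder's axis (axial gap 0.2 µm, lane gap 0.25 µm). When a lane exceeds
12 µm its outermost cell hops to an adjacent lane. This deterministic
repacking is a stand-in for real colony mechanics: it keeps the packing
overlap-free and visually colony-like, at the cost of occasional discrete
repositioning events that real cells do not show (the tracker treats these
as track-ending events, not divisions). Cells are flagged unanalyzable
once the population covers 30% of the field, mirroring the practice of
stopping analysis before crowding inhibits growth.

**Rendering.** Phase-contrast-like: dark capsules (intensity 0.25) with an
antialiased edge and a bright halo ring (0.80, 2 px wide, 1 px stand-off)
on a 0.55 background, Gaussian blur σ = 0.6 px, additive Gaussian noise
(σ = 0.02), 0.1 µm/px, 30-s frames, optional constant per-frame stage
drift. The halo stand-off keeps the edge profile symmetric around the true
boundary, so midpoint thresholding is unbiased to well under a pixel. The
ground-truth table (and optional label masks) is generated from the same
state that is rendered; dynamics and camera noise use separate RNG streams
spawned from one seed, so the truth table is bit-identical whether or not
frames are rendered. Fluorescence, photobleaching, pad mechanics and bleb
geometry are not modeled.

What passing against this generator shows — and does not. The movies have
exactly known answers, realistic contrast, touching cells, drift and
noise; they do not have real optics (defocus, shading, halo asymmetries),
segmentation-hostile morphologies, or colony mechanics. Pipeline scores
here bound algorithmic bias, not performance on arbitrary real data.

## Quantification pipeline

* **Registration**: integer-pixel phase cross-correlation of every frame
  against the first (plain normalization; the phase-whitened variant is
  uninformative on these low-texture images). Sub-pixel per-frame drift is
  recovered once it accumulates to a pixel; a confidence floor keeps the
  previous offset and warns on unregisterable frames.
* **Segmentation** (classical; a learned segmenter could drop in here, but
  the pipeline's contract is defined against the ground-truthed generator,
  which the classical method satisfies): Gaussian smoothing (σ = 0.6 px),
  Otsu split, then threshold refinement to the midpoint of the cell and
  background levels — Otsu alone is biased by the bright halos and shrinks
  the masks. Blank frames are detected by a contrast guard and return an
  empty mask. Morphological cleaning (min area 60 px², hole filling),
  then per-component marker-based watershed: markers are the high plateaus
  (> 0.75 × max) of the distance transform, so a single rod (one plateau)
  is never split while end-to-end touching cells (pinched neck) are.
* **Geometry**: the subpixel contour is the 0.5-level of the
  Gaussian-smoothed (σ = 0.75 px) label support. The centerline is the
  longest medial path of the contour interior rasterized at 3× (beating
  pixel quantization), spline-smoothed, and extended along its end
  tangents to the contour poles; length is its arc length, and the width
  profile is twice the exact distance from centerline points to the
  contour polygon. Near-round contours (no usable medial path) report the
  equivalent-circle diameter for both dimensions, so length ≈ width —
  the rounding phenotype's signature. Self-intersecting contours are
  rejected.
* **Tracking**: greedy frame-to-frame assignment by maximal mask overlap
  with a 10 px/frame displacement gate (cells are sessile on pads at 30-s
  frames) and a nearest-centroid fallback. Continuations must also be
  continuous in length (ratio in [0.75, 1.35]) and width ([0.7, 1.4]):
  jumps — typically two touching cells transiently merging into one blob —
  end the track rather than polluting a rate series. A one-to-two
  assignment is a division only if it is biologically plausible (each
  daughter ≤ 70% of the mother, combined length within 70–130% of it, and
  the mother tracked ≥ 2 frames); implausible splits (a neighbor sliding
  over the old footprint, or a transient merge splitting apart) end the
  track flagged. More than two successors flags and terminates.
* **Rates**: per track, λ = d log L/dt by central differences on a 5-frame
  (2.5-min) moving average of log length — the window is a smoothing
  choice, not a measured constant. Tracks end at divisions, so no sample
  spans one. Population curves are time-binned means with sample sd
  (ddof = 1) and per-bin n; division events are histogrammed in 5-min
  windows.

Known limitation: threshold segmentation erodes the cell poles by a
roughly constant fraction of a pixel, so measured lengths are short by a
small additive amount; because the deficit is additive, d log L/dt is
inflated by ≈ c/L — about +2% at these cell sizes. The per-bin recovery
tests bound this bias at under 5%.

## Problem sizes in the test and acceptance runs

The 24-hour hold is simulated at full size (172,800 samples; ~1 s). The
parameter-recovery benchmark movie is 70 min at 30-s frames, 16 founders
growing to ~170 cells (≈ 200+ tracked lineages, ~150 division events) on a
1024² field with slow diagonal drift — enough cells that the 5% recovery
tolerance is dominated by bias, not sampling. The filamentation benchmark
is 24 founders over 45 min with the shift at 20 min. These sizes were
chosen so the full suite builds both movies once (session fixtures) and
analyzes them end to end in a few minutes.

## Degenerate inputs and tie-breaks

Equal-temperature calibration pairs, non-positive resistances, negative
time steps, empty traces, non-monotone time, constant "transitions",
blank frames, absent labels, 1-px regions and self-intersecting contours
all raise typed errors (or, where the field's convention is lenient —
blank frames — return empty results). PWM rounding is half-up. Watershed
marker plateaus use a relative threshold so scaling image intensity does
not change the segmentation. The division-asymmetry draw is clipped at
±20% to keep both daughters viable.
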