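# Methods

## The classification model

`triact` classifies thigh-worn tri-axial accelerometry into three behaviour
classes — dynamic, standing, and sedentary (sitting/lying) — with a
transparent two-level decision tree operating on fixed, non-overlapping
windows.

Each axis of the raw signal (in g) is modelled as the sum of sensor noise,
body acceleration (BA) produced by movement, and gravitational acceleration
(GA) reflecting the segment's orientation. The pipeline is:

1. **Noise removal.** A centered moving average with span 0.12 s
   (3 samples at 25 Hz; the rounded span is forced odd so the filter is
   symmetric). Edges use the shrunken window rather than padding.
2. **Component separation.** A 4th-order Butterworth high-pass at 1 Hz
   yields BA; a 4th-order Butterworth low-pass at 1.25 Hz yields GA. Both
   are applied per axis to the moving-average output.
3. **Segmentation.** Non-overlapping windows of N = round(WS × rate)
   samples; the trailing partial window is discarded (features are defined
   only over complete windows).
4. **Features.** Per window j:
   - SMA_j = (Σ_axes Σ_i |BA_i|) / WS, in counts per second (cps);
   - GA_x,j = (1/N) Σ_i GA_x,i, the mean longitudinal gravity component.
5. **Decision tree.** DYNAMIC if SMA_j ≥ PA Th; otherwise STANDING if
   sign · GA_x,j ≥ SO Th; otherwise SEDENTARY.

### Adjustable parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| WS | segmentation window size | s | 2 |
| PA Th | physical-activity (SMA) threshold | cps | 7 |
| SO Th | sensor-orientation threshold on GA_x | g | 0.8 |

The defaults are the settings optimized for healthy elderly with the sensor
on the upper leg. SO Th = 0.8 g corresponds to a thigh angle of
arccos(0.8) ≈ 36° from vertical: a static window with the thigh within 36°
of vertical is standing. `LEGACY_PARAMETERS` (WS 1 s, PA Th 5 cps) is the
predecessor setting for chronic organ failure patients and the starting
point of the optimizer.

### Conventions the model itself does not fix

- **Counts.** One count ≡ one g-second of rectified body acceleration
  summed over the three axes; SMA is therefore normalized by the window
  length, making cps comparable across window sizes and sampling rates.
  A `count_scale` multiplier (default 1) can match other hardware
  conventions.
- **Boundaries.** Both threshold comparisons use ≥ (a window exactly at
  PA Th is dynamic; exactly at SO Th is standing). The boundary has measure
  zero in practice, but a fixed convention keeps the classifier
  deterministic.
- **Zero-phase filtering.** Analysis is offline, so both Butterworth
  filters run forward–backward (`sosfiltfilt`); causal filtering would
  phase-shift BA relative to GA and misalign the two branches on the window
  grid. The stated order is the per-pass design order. `FilterConstants
  (zero_phase=False)` switches to causal filtering.
- **Axis polarity.** +X points toward the hip, so upright standing gives
  GA_x ≈ +1 g; `orientation_sign=-1` handles an inverted sensor.
- **Effective window duration.** Class totals are counted as
  windows × N/rate. When WS × rate is an integer (every value swept here)
  this equals WS exactly; for fractional N it keeps time conservation
  exact: Σ class totals + dropped tail = covered recording duration.
- **Edge transients.** Zero-phase filtering leaves ~1 s transients at
  recording ends; classification uses the full output since the effect on
  multi-minute recordings is negligible. Filter property tests exclude a
  1 s guard band (2 s for the deep-stopband check, which is a steady-state
  property).

## Agreement statistics

Per participant and class, percentage error compares total classified time
to the gold-standard annotation total:

    PE  = 100 · (T_gold − T_algo) / T_gold,   APE = |PE|

Positive PE is underestimation. PE cancels over/under-estimation across a
group; APE does not and therefore tracks individual-level error. Group
values are reported as median with a 95% CI from binomial order statistics
(distribution-free, conservative: true coverage ≥ 95%); for n < 6 the
exact method cannot reach 95% and the data range is returned with a
warning. Agreement between 90% and 110% (|PE| ≤ 10, closed band) counts as
acceptable. Classes with zero gold time for a participant are skipped with
a warning — the denominator is undefined.

Inter-method/inter-observer machinery: Bland–Altman limits of agreement
(mean difference ± 1.96 × sample SD of differences) and ICC(2,1) — two-way
random effects, absolute agreement, single measures — computed from the
two-way ANOVA mean squares

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)).

Degenerate all-identical matrices return 1 by convention.

## Parameter optimization

`optimize_sequential` mirrors a two-stage procedure: sweep WS (default
1–10 s) at the legacy PA Th of 5 cps, pick the best, then sweep PA Th
(default 3–12 cps) at that window size. SO Th is never varied — for a fixed
wear location it is a geometric constant. The objective at each grid value
is the **sum over the three classes of the group median APE**; summing
treats the classes equally and uses the individual-level error measure.
Ties break toward the smaller parameter value (shorter windows straddle
fewer activity transitions; a lower threshold is the more sensitive choice
at equal error). Sequential search is a deliberate simplification — it
finds a setting meeting the ≤10% criterion, not the joint optimum; a full
2-D sweep is a straightforward composition of `evaluate_grid` calls if
needed. Recordings are filtered once per sweep and the BA/GA branches
reused, since the filters do not depend on the swept parameters.

## Synthetic data: what it emulates, and what it does not

`simulate` generates labeled recordings so every stage is testable without
human data. Per activity segment:

- **Gravity**: a constant vector at `thigh_angle` θ from vertical,
  g_x = cos θ, confined to the X–Z plane by default (only g_x enters the
  classifier; a mediolateral tilt option exists for robustness tests).
- **Movement**: dynamic segments add sinusoids at the gait frequency and
  its first harmonic across the three axes. Amplitudes are calibrated
  empirically: a unit-amplitude probe is passed through the pipeline's own
  moving-average and high-pass filters and the measured cps fixes the
  scale, so a requested `ba_intensity` measures within ~10% (typically
  ~2%) after filtering for intensities in 5–30 cps. This avoids an
  analytic rectified-sine/filter-gain derivation that would duplicate
  pipeline code.
- **Noise**: white Gaussian, default SD 0.01 g, which yields ≈ 0.3 cps in
  static segments — far below the smallest threshold swept (3 cps).

Protocol builders:

- **Fixed protocol** (`generate_fap`): prescribed order and durations —
  standing 120 s (θ=5°), walking at two speeds and overground
  (120 s each, 8/18/15 cps), biking (120 s, 12 cps, θ=60°), sitting 180 s
  (θ=85°), lying 120 s (θ=90°); class totals 480/120/300 s. Walking
  intensities are plausibility choices (true elderly-gait cps on this
  class of hardware is not established); all are configurable.
- **Simulated free-living** (`generate_sfp`): a seeded random sequence of
  ADL-like bouts (uniform 20–180 s, mixed classes) with short 5–15 s
  dynamic transfers inserted between consecutive non-dynamic bouts. The
  `mixed_adl` option interleaves 2–5 s quiet standing micro-pauses inside
  bouts *labeled* dynamic — reproducing the rater-definition ambiguity of
  household ADLs (e.g. setting a table), which is the dominant source of
  free-living dynamic error.
- **Separation benchmark** (`generate_separation_cohort`): long alternating
  bouts with dynamic activity at 12 cps and noise at 0.07 g (static
  ≈ 2 cps), so any threshold between the two levels classifies perfectly
  and the optimizer should land on that plateau.

Deliberately **not** modelled: biomechanically realistic gait waveforms,
sensor error models (bias, cross-talk, saturation), postural sway spectra,
gradual posture transitions, and annotation noise. Passing tests on this
generator therefore demonstrate that the pipeline implements its contracts
and recovers known structure — not field accuracy on real elderly data,
which requires a human validation study.

## Numerical choices and degenerate inputs

- Window count = floor(samples / N); recordings shorter than one window
  yield a valid empty series.
- SMA of an all-zero window is exactly 0; empty windows raise.
- Out-of-range samples (> 8 g) are hard I/O errors, never clipped —
  silent clipping would bias SMA downward.
- Recording CSVs round-trip losslessly (17 significant digits).
- The median-CI lower rank l is the largest with Binomial(n, ½)
  CDF(l−1) ≤ 0.025; the interval is (x₍l₎, x₍n+1−l₎).
- All randomness flows through `numpy.random.Generator` seeded per
  subject via `SeedSequence`; identical seeds give bit-identical
  recordings.

## Problem sizes

Defaults keep everything interactive: 15-minute recordings at 25 Hz
(22 500 samples), cohorts of 10 subjects, full 10 × 10 sequential sweeps in
a few seconds on one core. The test suite runs in under 10 s; the
acceptance script in a few seconds.
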