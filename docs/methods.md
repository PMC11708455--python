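# Methods

This note records the models, conventions and numerical choices behind the
package, in the order the data flow through it.

## The measurement problem

Four scalar indices are computed from a resting 12-lead ECG:

* **PWD** (ms) — P-wave duration, onset to offset. Reported globally as the
  maximum across measurable leads (consistent with the dispersion
  definition below, and with the ~130–140 ms magnitudes such cohorts
  report). A mean-across-leads rule is selectable.
* **PWV** (mV) — P-wave voltage, distance from the isoelectric line to the
  P peak. Reported as the **sum** over the 12 leads by default: a combined
  12-lead analysis printing ~1.2 mV is an order of magnitude above any
  single-lead P amplitude (~0.1 mV), and the sum reproduces that scale.
  `max` and `mean` are selectable.
* **PWDisp** (ms) — dispersion, max − min of per-lead durations.
* **PTFV1** (mV·ms, ≤ 0) — terminal force in V1: −(maximum depth of the
  terminal negative phase below the isoelectric line) × (its duration).
  Clinical reports print this quantity under the label "mm.s"; the printed
  magnitudes (≈ −3) correspond to mV·ms, not to the classical mm·s at
  10 mm/mV chart gain (which would be ≈ −0.03). The package computes in
  mV·ms and exposes `CLASSICAL_MM_S` for conversion.

## Acquisition model and filtering

Records are +/-5 mV, 16-bit (quantization step 10 mV / 2^16 ≈ 0.1526 µV
per LSB), band-pass filtered 1–50 Hz with a mains notch. The
band-pass is a zero-phase Butterworth (default order 8) and the notch a
zero-phase second-order IIR at 50 Hz (configurable to 60 Hz), Q = 30.
Zero-phase application protects fiducial timing.

Two consequences of the 1-Hz high-pass shape everything downstream:

1. At 75 bpm the beat fundamental is 1.25 Hz — just above the cutoff. A
   shallow (order-4) high-pass removes ~30% of that fundamental; what is
   removed reappears as a smooth, beat-periodic baseline drift of tens of
   µV under the P-wave. Order 8 (the default) reduces the removal to
   ~14%, and the remaining drift is handled by the local isoelectric-line
   fit described below. This is why the filter order is deliberately
   steep.
2. The 50-Hz low-pass smears a small undershoot backward (zero-phase)
   from the QRS upstroke; measurement windows therefore keep ≥ ~18 ms
   clear of the estimated QRS onset.

## Beat detection and template averaging

R peaks are found on lead II by thresholding the moving-averaged squared
derivative (Pan–Tompkins style), refined to the local signal maximum, with
a 250-ms refractory period; each QRS onset is estimated by walking back
down the upstroke to 2% of the R amplitude. Twenty consecutive beats
(configurable) are averaged per lead after excluding beats whose preceding
RR interval deviates more than 20% from the record median; segments are
aligned on the R peak and span from 60% of the median RR before it to the
QRS onset. Averaging suppresses white noise by √n (verified: residual SD ≈
σ/√20 within 15%).

## Delineation

Per lead, on the averaged template:

* **T peak** — maximum of the leading 40% of the window.
* **P peak** — the most prominent lobe between the T peak and QRS onset
  whose width at half prominence is ≥ 15 ms; narrower deflections
  (spikes, notches) are ignored. Positive lobes are preferred; a fully
  negative P-wave is delineated on the inverted signal.
* **Onset / offset, chord (knee) rule** — the interior sample of maximal
  perpendicular distance to the straight chord from the T peak to the P
  peak (onset; ties to the later sample), and mirrored against the chord
  from the P peak to the QRS onset (offset). The knee lands where the
  signal slope equals the chord slope — between ~2.2σ and ~3.5σ from a
  Gaussian lobe's center depending on chord geometry — so it is used as a
  robust localizer, not as the final fiducial.
* **Isoelectric line** — fitted locally through two flat flanks (TP
  segment left of the estimated onset; PR segment 18–45 ms before QRS
  onset) with basis {1, cos(2πt/RR), sin(2πt/RR)}: the drift left by the
  high-pass is exactly beat-periodic, so this basis represents it without
  bias; a quadratic is used when the beat period is unknown. On an
  undistorted record both reduce to the flat TP level, which is the
  classical definition of the isoelectric reference.
* **Support refinement** (default on) — each fiducial is snapped to the
  edge of the contiguous region where the excursion above the isoelectric
  line exceeds e^{-2} ≈ 13.5% of the P prominence, with a 5-ms hysteresis
  against noise dips and nearest-sample rounding at the crossing.
* **V1 terminal phase** — the contiguous run below the isoelectric line
  following the positive phase, delimited at 13.5% of the trough depth;
  the search stops 20 ms short of QRS onset (low-pass pre-undershoot).
  Phases shallower than 10 µV or 6% of the P prominence are reported as
  absent: below that the threshold sinks under the residual noise floor
  and the boundaries are not measurable. For a biphasic V1 wave the P
  offset is the end of the terminal phase (the chord rule's
  maximal-distance point for a biphasic wave is the trough, not the wave
  end).

**Why 13.5% (±2σ)?** Durations need a convention for where a smooth wave
"ends". At a 1.1% (±3σ) level, the tail slope of a σ ≈ 30 ms lobe is
~0.2 µV/ms, so every µV of residual noise, quantization or drift moves the
crossing by ~5 ms — fiducials are not reproducible there, by any rule. At
13.5% the slope is ~1 µV/ms and edges are stable to ~1–2 ms. The synthetic
generator defines its analytic durations with the same ±2σ convention, so
ground truth and measurement are commensurable by construction.

Manual correction of fiducials is replaced by `AnnotationOverride`:
caller-supplied indices replace computed ones after ordering validation,
and are honored verbatim downstream.

## Synthetic cohort generator

Each beat is a sum of lobes on a flat baseline: one positive Gaussian P
lobe per lead sharing a common onset; in V1 an additional negative
Gaussian lobe (the terminal phase) separated from the positive lobe by a
10-ms flat gap so each phase's edges are measurable; a triangular QRS
(1 mV, 80 ms); a Gaussian T (0.1 mV, 150 ms support). Default heart rate
is 75 bpm: with the 60%-of-RR averaging window the preceding T peak must
fall inside the window, which fails at 60 bpm with a physiological QT.
The PR segment keeps 80 ms between the longest P offset and QRS onset so
a clean right baseline flank exists. Sampling rate defaults to 1 kHz.

Artifacts: per-lead white noise (10 µV SD), baseline wander (50 µV at
0.25 Hz) and mains hum (20 µV at 50 Hz), each with per-lead random phase.
Records are reproducible bit-for-bit given a seed.

A cohort config specifies, per arm (success/fail) and phase (pre/post),
population mean and between-patient SD of the four analytic parameters;
post values are pre plus an independent delta. Per-patient morphology is
solved in closed form: fixed per-lead duration fractions spread per-lead
PWDs between lead II (longest) and V2 (shortest); fixed per-lead
amplitude weights split the PWV sum; V1's terminal-phase duration is an
independent structural draw (52 ± 8 ms), its depth then fixed by
|PTFV1|/duration. Feasibility conflicts (a short P-wave that cannot hold
the terminal phase) are absorbed by non-target degrees of freedom — the
patient's V1 duration fraction (0.1–0.5) and terminal-phase duration —
never by resampling the calibrated target draws; extreme tails are
clipped at documented bounds carrying a few per mille of mass.

**Moment matching.** With `moment_match: true` (the packaged calibration)
each drawn vector is standardized to exact sample mean and SD before
scaling, so the arm-level calibration targets hold at the study's finite
n (43/29), not only in expectation. The type-I-error property deliberately
uses `moment_match: false`, because it is a statement about sampling
variability.

**Packaged calibration** (`pwave/data/calibration.yaml`): population
means equal the reported arm-level values (success PWD 136.7→123.5 ms,
PTFV1 −3.1→−4.4 mV·ms, PWV 1.2→1.3 mV, PWDisp 29.7→28.2 ms; fail
135.4→125.3, −2.9→−2.7, 1.3→1.34, 30.2→28.6). Between-patient SDs are
chosen so that, at n = 43/29, the paired and unpaired comparisons
reproduce the reported significance pattern (PTFV1: significant fall in
the success arm, no change in the failed arm, significant between-arm
difference of the changes; PWD: significant fall in both arms without a
between-arm difference; PWV/PWDisp: no significant changes). The
delta SDs implied literally by the printed p-values (e.g. 32.5 ms for
PWD) would push a visible fraction of post draws outside morphology
feasibility, so SDs of the same order were chosen that keep the pattern
while keeping clip bias on arm means well below the acceptance bands.

**What the generator does not emulate:** ectopy and rhythm disturbance,
heart-rate variability (irrelevant to beat-averaged measurands),
respiration modulation, electrode-motion artifacts, per-lead QRS/T
morphology differences, negative P-waves in aVR, and demographic
covariates. Passing tests therefore demonstrate the measurement chain's
correctness on compact smooth waves under additive stationary artifacts —
not performance on pathological clinical recordings.

## Statistics

Continuous summaries are mean ± SEM (SD/√n, ddof = 1). Matched data use a
paired t-test when the D'Agostino–Pearson omnibus K² test (n ≥ 8) does
not reject normality of the differences at 0.05, otherwise the Wilcoxon
signed-rank test (normal approximation); unmatched data use Welch's
t-test, falling back to Mann–Whitney. Every result records which test
ran. Two-sided p-values; 0.05 threshold; no multiple-testing correction
(matching the emulated report's practice). Between-arm comparisons act on
pre-to-post change scores.

The intraobserver protocol measures a set of ECGs twice — the second pass
with seeded Gaussian jitter (default SD 2 ms) applied to onset, peak,
offset and trough through the override hook, emulating human
re-annotation — and reports, per parameter, the mean absolute inter-run
difference, its SEM, and a percentage of the parameter's mean absolute
value (the report it emulates states "a percentage" without defining the
denominator). 22 ECGs × 12 leads × 20 beats = 5280 P-waves enter the
protocol.

## Problem sizes and numerical choices

* Calibrated study runs: 72 patients × 2 phases × 60-s records at 1 kHz
  (~20 s on one CPU). The acceptance script reruns exactly this.
* The type-I-error property uses a reduced null cohort (12 vs 12
  patients, 10-s records at 500 Hz, 8-beat averaging) over 400 seeds: the
  null rejection rate of a t-test is free of n, and this size makes the
  400-seed sweep tractable (~4 min).
* The consistency check enlarges the success arm tenfold (n = 430) on
  short records.
* Ties in the knee rule break toward the P-wave; support-edge crossings
  round to the nearest sample; all indices are 0-based template offsets,
  durations are (index difference)/fs × 1000 ms.
* Degenerate inputs raise typed errors: flat signals, < n_beats+1 beats,
  empty peak windows, degenerate chords, zero-variance paired data,
  out-of-range samples.

## Known limitations

* Global PWD under the max rule inherits the worst single-lead error;
  low-amplitude leads (~0.04 mV) occasionally mis-delineate under noise,
  which inflates a patient's dispersion. Arm-level means remain within
  the calibration bands, but per-patient dispersion is the noisiest
  output (as in the emulated intraobserver report, where PWDisp showed
  the highest variability).
* PTFV1 for terminal phases shallower than ~10 µV is reported as 0; the
  generator avoids drawing such patients, real data would not.
* The chord rule without support refinement is geometry-dependent; it is
  retained for transparency, not accuracy.
* The statistical layer reproduces a significance *pattern*, not printed
  p-values: p-values are sample statistics and the emulated cohort's raw
  data are not available.
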