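# Methods

## Scope and data model

The package analyses skeleton time series of 25 named anatomical landmarks
(pelvis-to-head axial chain plus paired arm/leg landmarks, the Kinect-V2
vocabulary) sampled at a nominal 30 Hz.  The coordinate frame is fixed:
X medio-lateral (subject's right positive), Y vertical (up), Z
anterior-posterior (into the scene; a subject walking toward the camera has
decreasing Z).  Internally everything is meters and seconds; centimeters,
degrees and steps/min appear only at reporting.

Six tasks are covered, with the repetition scheme of the original protocol:
one recording each for quiet stance (POCO, 20 s eyes open + 20 s eyes closed,
one cue at the phase change) and stepping in place (SIP, 40 s), and three
recordings each (one measurement, two immediate repetitions) for the two
straight walks (SCSW, SMSW), the line walk (SLW) and sit-stand (SAS, two
cues) — 14 recordings per subject.  Walk length is fixed at 4 m, the sensor's
usable range.

## Preprocessing

Timestamps from depth sensors are jittery, so every extractor first linearly
resamples to exactly 30 Hz and applies a zero-phase 4th-order Butterworth
low-pass at 6 Hz (forward-backward, no phase distortion).  Sequences shorter
than 1 s are rejected.  Two extraction-side refinements matter numerically:

* **Sub-frame peak timing.** Step events are localized by parabolic
  interpolation through each detected peak and its neighbours.  Without
  this, 30 Hz grid quantization injects ~3% spurious variability into
  inter-step intervals — fatal for the arrhythmicity parameter, whose
  ground truth can be 0.
* **Sway band.** The sway-angle trajectory gets an additional zero-phase
  1 Hz low-pass.  Quiet-stance sway is dominated by sub-1 Hz content, while
  the angular path length (sway speed) grows without bound with white
  tracking jitter; at the default 1 mm landmark noise the 1 Hz band keeps
  sway speed within ~5% of ground truth where the 6 Hz band alone was off
  by a factor of 4–5.

## Parameter definitions

**Posturography (POCO).** Sway is the movement of the spine base relative to
the closed-feet stance: the two-component (ML, AP) angular displacement about
the ankle midpoint fixed at phase start — component-wise arctangent of
horizontal displacement from the phase-mean position over the spine-base
height above the ankles.  Sway speed is the mean angular path length per
second; the deflection range is the diameter (maximum pairwise distance) of
the angular trajectory.  Each Romberg ratio is closed-phase / open-phase;
the published values exceed 1 together with closed-phase sway exceeding
open-phase sway, which fixes this direction even though the original table
caption reads "open eye to closed eye".  A value with a zero open-phase
denominator is flagged missing rather than infinite.  A 0.5 s guard band on
each side of the cue is excluded from both phases: the eyes-closing instant
carries a movement artifact (and, in simulation, low-pass smear of the phase
change) that otherwise bleeds across the boundary.  On a circular sway path
of angular radius r and revolution rate f the definitions give closed forms
used throughout the tests: mean speed 2·pi·f·r, range 2r.

**Step detection.** Per side, events are local maxima of the forward
excursion signal — ankle walk-direction displacement relative to the spine
base for walks, knee AP-V displacement magnitude relative to its standing
baseline (per-coordinate median) for stepping in place.  Peaks require a
prominence of 25% of the signal SD (scale-free) and a per-side gap of
0.25 s; fewer than four events or a non-alternating merged train is an
error.

**Walks.**  Gait/progression speed is the least-squares slope of the
spine-base advance over the central path, excluding 0.5 m after the start
and before the stop (boundary and filter-edge effects).  Cadence is
60 / mean inter-step interval of the merged event train; step length is the
mean AP separation of the ankles at step events (for a steady-state gait the
leading-trailing separation at a forward extremum).  Line-walk trunk sway is
the SD of the ML inclination of the shoulder-center-minus-spine-base vector
from vertical; arm variability is the SD of the wrist-minus-shoulder
elevation angle, pooled over sides as the root mean variance.  A sinusoidal
angle of amplitude a has SD a/sqrt(2) — the generator/extractor consistency
check.  Values are averaged over the three recordings.

**Sit-stand (SAS).**  Seated and standing levels are spine-base height
medians over the pre-cue span and the second half of the inter-cue span.
Each transition window runs between the crossings of 5% and 95% of the
seated-to-standing height difference (linearly interpolated between frames),
searched after the corresponding cue; a height difference below 10 cm is "no
transition detected".  On a linear height ramp of duration T the rule yields
0.9·T exactly; for the smoothstep profile (3u²−2u³) the fraction is ~0.7298
(computed numerically, validated against dense sampling).  Transition time
is the window length; trunk deflection is the AP range of the
shoulder-center-minus-spine-base vector within the window; hand deflection
is the larger of the two hands' AP ranges — the maximum is deliberately
sensitive to unilateral arm use.

**Stepping in place (SIP).**  From the knee event train: cadence as above;
per-side amplitude is the mean peak displacement magnitude; the knee
amplitude is the mean of sides; asymmetry is |A_L − A_R| / max(A_L, A_R) ×
100; arrhythmicity is 100 × CV (n−1) of the merged inter-step intervals.
The asymmetry and arrhythmicity definitions are not nailed down by the
original protocol text; these common forms are isolated behind single
functions (`amplitude_asymmetry`, `arrhythmicity`) for easy replacement.

All extracted magnitudes are invariant to rigid horizontal translation of
the scene and to constant time shifts, and covariant under time rescaling
(times scale with c; cadence and sway speed with 1/c; amplitudes unchanged)
— both are property-tested.

## Synthetic data

The original raw recordings were never released; the generators are the
package's stand-in and are deliberately minimal kinematic models, not
biomechanics.  A rigid standing pose (classic anthropometric segment
fractions of body height) is animated with exactly the signal each extractor
measures:

* POCO: everything above the knees traces a circular angular path about the
  ankle midpoint, radius and rate per phase; feet stay planted.
* Walks: the pelvis advances at the constant speed implied by
  speed = cadence × step length / 60 (steady state, no gait initiation);
  ankles oscillate in the walk direction around the pelvis at half the
  cadence with amplitude step_length/2, in antiphase.  The line walk adds
  sinusoidal ML trunk lean and arm-elevation oscillation.
* SAS: pelvis height follows seated → smoothstep (or, for closed-form
  tests, linear-ramp) rise → stand → fall, with AP trunk and hand excursion
  bumps placed strictly inside the 5%/95% detection window so the extracted
  deflections equal the generating amplitudes.
* SIP: alternating raised-sine knee-lift bumps in the AP-V plane; step
  intervals are drawn from a seeded normal with stated mean and CV.

Landmark jitter is isotropic Gaussian, independent per frame, default SD
1 mm — the simplest defensible sensor-noise model.  It reproduces neither
temporally correlated tracking drift, occlusion dropouts, nor per-landmark
noise heterogeneity of real depth-camera tracking, so a green recovery test
establishes correctness of the definitions, not field robustness.

Calibration inverts the extractor definitions: cohort parameter targets
(published means/SDs) map to generating values (sway radius = range/2, rate
= speed/(2·pi·radius), SAS profile duration = target time / window fraction,
SIP side amplitudes from mean and asymmetry, and so on), with targets
clipped to physically workable bounds.  The walks calibrate cadence and
step length and let speed emerge, because the published group means violate
the steady-state identity (116.1 × 0.6719 / 60 ≈ 1.30 m/s against a printed
1.16 m/s comfortable-speed mean — plausibly acceleration phases on a 4 m
path, which the steady-state generator deliberately does not model).

Parameter-level cohorts draw stature from truncated normals at the
published moments (truncation at the published ranges) and the 23 parameters
from normals at the published means/SDs.  Stature-linked parameters (step
length, both walk speeds, standardized height coefficients 0.5/0.4/0.4 by
default) are generated as mean + sd·(b·z_height + sqrt(1−b²)·ε) with
z_height standardized by the *truncated* stature moments, which preserves
the marginal mean/SD exactly and carries exactly the stated coefficient.
Parameter values are intentionally not truncated to their physical support:
the table emulates the published moments, and truncation would bias the
effect sizes the comparison stage is calibrated against.

Reproducibility: one global seed expands through `numpy.random.SeedSequence`
into per-cohort, per-subject and per-(task, repetition) child streams, so
identical configuration and seed give byte-identical recordings, tables and
report files.

## Statistics

* Descriptives: sample SD (n−1); CV = SD/mean, undefined for non-positive
  means; Shapiro-Wilk per cohort per parameter, reported but never gating
  the t-tests (the original analysis proceeded despite non-normality).
* Cohen's d from summary moments: d = (mean₂ − mean₁)/s_pooled with n−1
  weights; equal group sizes reduce to sqrt((sd₁²+sd₂²)/2).  Group coding
  0 = Japanese, 1 = German, so signs read German-minus-Japanese.
* t-test: pooled-variance Student's t by default (per the original table
  footnote), Welch behind a flag; two-sided.
* Sex ratio: Pearson chi-square without continuity correction (with the
  correction the published 2×2 gives p ≈ 1 instead of the printed .776).
* Adjusted regression: OLS of the z-scored outcome on z-scored group (0/1),
  height and weight; standardized betas with t-based 95% CIs; R² and the
  overall F-test p; collinearity flagged by design-matrix condition number.
  The CI construction is not documented in the original report; the
  t-interval on the standardized fit is recorded in the output metadata.
* Matching: filter candidates to age 20–40 and BMI 18–29, then per sex
  stratum greedy nearest-neighbour on BMI, ties broken toward the shorter,
  then lighter candidate (matching a smaller-statured reference).
* No multiple-comparison correction anywhere, matching the exploratory
  design; significance marking at p < .05.

## Verification against the published tables

`verify_printed_effects` recomputes every Cohen's d (4 subject
characteristics + 23 parameters) and every CV cell from the printed group
means/SDs.  Printed inputs are rounded to their last decimal, so each
recomputed quantity is an interval (corner propagation of half-ULP boxes),
and a check passes when the printed value falls within that interval
expanded by ±0.02 for d and ±0.005 plus the printed CV's own half-ULP for
CV.  All 27 d cells and 45 of 46 CV cells reproduce.  The German line-walk
trunk-sway CV does not: its printed mean/SD give SD/mean ≥ 0.488 under any
rounding, against a printed CV of 0.47 — an internal inconsistency of the
source table, which the verifier reports as a fail row by design.

## What is not reproducible

The published adjusted-regression table (R², F-p, standardized betas/CIs)
and the count of parameters with group effects after adjustment depend on
the individual-level data, which were never deposited.  They are covered by
property-based substitutes instead: exact equivalence of the regression with
a normal-equations oracle; type-I calibration of the group effect under a
null simulation (rejection rate ≈ alpha within Monte-Carlo error over 1000
replicates); recovery of a generating standardized height coefficient
(bias < 0.05 at n = 50 over 500 replicates); and stochastic reproduction of
the published unadjusted effect sizes — over 200 seeded cohort-pair
replicates, the mean recomputed d per parameter stays within ±0.05 of its
sampling expectation d/J(df) (pooled-d small-sample bias, J = 1 − 3/(4df−1)),
with RMS single-replicate deviations within the ±0.45 sampling error of d
at n = 25 per group.

## Known limitations

* The kinematic simulators are signal generators, not physically valid
  whole-body motion; joint trajectories outside the measured signals are
  placeholders.
* POCO deflection range is a maximum statistic and carries an upward noise
  bias (~10% at 1 mm jitter) that no fixed filter removes; comparisons at
  matched noise levels remain valid, absolute values at high jitter do not.
* The skeleton CSV dialect is this package's own (the original export
  format is undocumented); only the subjects/parameters CSV schemas are
  shared surfaces.
* Cue times are trusted metadata; no audio-event detection is attempted.
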