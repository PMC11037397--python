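# Methods

## Scope and design of the pipeline

The package models a cued-walking protocol on a 10 m walkway. Each
participant contributes two static head-orientation trials and 30 cued
walking trials: 9 gait-speed trials (real-world speed line, AR speed line,
AR eye-height "bird" × slow/preferred/fast), 9 step-length trials
(real-world targets, AR footprints, AR footprints with sound ×
short/preferred/long), 6 obstacle-crossing trials (real-world, AR ×
15/30/45 cm depth) and 6 hurdle trials (real-world, AR × 5/10/15 cm
height). Task order is fixed; condition order within a task is randomized
per participant from a seed. Hurdle (crossing-height) trials are generated
but flagged `analysis_included=False` and never analyzed; three baseline
walks (two without the headset, one with it) are emitted as calibration
trials outside the 30-trial count. The pipeline reports its own explicit
trial accounting rather than a single "remaining trials" figure.

Speed and step-length modulations are anchored to each participant's
preferred gait (baseline ± 20 cm/s; baseline ± 15 cm), so imposed values
differ between participants while modulation *magnitudes* do not.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
full-body biomechanics. Per trial:

* **Step plan.** Footfall locations along the walkway are drawn from the
  imposed value plus a condition-level systematic adherence bias plus
  Gaussian execution noise (per step for lengths, per trial for speed).
  Crossing trials lengthen the first step, and the first step after the 5 m
  obstacle, to clear the obstacle depth plus 15 cm margins on either side.
  Feet alternate starting with the profile's leading limb.
* **Timing.** Each step of length L takes L/v seconds. For speed trials v
  is the executed speed (imposed + bias + noise) with steps at the
  preferred length; for step-length trials the cadence is preserved — the
  step duration stays at its preferred value, so the executed speed scales
  with the imposed step length. (Keeping speed constant instead would push
  short-step participants toward ~4 steps/s, which real walkers do not do.)
* **Tracks.** Feet are stationary during stance and advance along a
  smoothstep profile during a 0.4 s swing; the spine-shoulder point
  linearly interpolates the mid-feet position at each step completion,
  which makes its steady-state velocity exactly the executed speed (so the
  noise-free 3–9 m speed window is exact by construction). All tracks are
  sampled at 30 Hz (the Kinect-v2 convention; configurable) with optional
  Gaussian marker jitter (default SD 3 mm), and clipped to the walkway.
* **Head pitch.** Floor cues are fixated a preview distance ahead of the
  feet (default 2.4 m), giving pitch `atan(eye_height / preview)` ≈ 34° for
  a 1.65 m eye height — chosen as a plausible value in the range published
  head-orientation medians occupy, not fitted to them. The eye-height bird
  cue gives 0°. The static task fixates ground lines at 10–280 cm with
  pitch `atan(eye_height / distance)` per line, framed by straight-ahead
  (0°) calibration segments. Pitch noise default 2° SD.
* **Cohort.** Baselines are drawn per participant (speed 127 ± 16 cm/s,
  step length 68 ± 10 cm, eye height 1.65 ± 0.05 m — the first two match
  the scale of published cued-walking cohorts); headsets alternate
  HL2/ML2 for an even split. Per-participant and per-trial random streams
  derive from the master seed via `SeedSequence` spawn keys, so enlarging
  the cohort never reshuffles earlier participants.

Execution-noise defaults (speed 6 cm/s per trial, step 2 cm per step) were
set once so that trial-level executed−imposed variability lands on the
scale implied by published equivalence tables; adherence bias defaults to
zero (an unbiased walker), since systematic over/undershoot is a finding,
not a design input. What passing tests show is therefore that the *method*
recovers what the generator encodes at realistic noise levels — not that
real patients behave this way: the generator has no freezing episodes, no
fatigue or learning trends, no missing-marker dropouts, and its
within-trial kinematics are schematic between footfalls.

## Event detection

Stances are detected per foot by thresholding the anterior–posterior
velocity: the position is smoothed with a 3-sample moving average (without
it, 5 mm marker jitter punches through the threshold mid-stance and splits
stances), differentiated by central differences, and maximal intervals with
|v| < 0.2 m/s lasting ≥ 0.15 s become stances after merging gaps < 0.05 s.
The step location is the median *raw* position within the stance. The
detector is translation-equivariant and insensitive to sampling-rate
doubling; thresholds are exposed in `RunConfig`. Bilateral merging warns —
but does not fail — on alternation violations; trials where detection or a
window precondition fails yield a null measurement with an explicit reason
and are excluded analysis-by-analysis.

## Outcome measures

* gait speed: 600 cm / (t(9 m) − t(3 m)) from the spine-shoulder track,
  crossing times linearly interpolated;
* step length: median AP difference of consecutive (bilaterally pooled)
  step locations with both endpoints in [1, 9] m — windows are closed
  intervals, feet are pooled without laterality;
* crossing step length: at initiation, first step location minus the median
  standing position of the leading limb; halfway, first location past 5 m
  minus last before 5 m;
* walking head pitch: median pitch while the headset is between 3 and 7 m,
  minus a baseline; the baseline defaults to the participant's static-trial
  straight-ahead median (configurable to zero), since a per-walk
  calibration segment is not guaranteed to exist;
* static head pitch: per line, median pitch in the fixation window minus
  the pooled straight-ahead median.

## Statistics

**TOST.** Paired equivalence bounds follow the 25 % rule:
Δ = 0.25 × modulation magnitude (5 cm/s, 3.75 cm). With d = executed −
imposed, t_L = (d̄ + Δ)/SE tests H0: d̄ ≤ −Δ and t_U = (d̄ − Δ)/SE tests
H0: d̄ ≥ +Δ; equivalence requires both one-sided p's < α. A zero-variance
difference vector is flagged degenerate, with no test. The exact identity
t_L + t_U = 2t of the three statistics is used as a consistency property in
the tests.

**Split-plot ANOVA.** One between-subjects factor (headset) and any number
of fully crossed within-subject factors. Each within-involving effect is
computed on orthonormal (normalized Helmert) contrast scores z: the effect
SS from the grand mean of z, the effect × group SS from group differences,
and the error from residual z variation (effect × subjects-within-groups).
With unequal group sizes the effect SS uses the unweighted-means (Type
III-style) intercept, matching common ANOVA software; group-effect and
error SS are the standard one-way quantities. ε_GG = (tr S)² / (d·tr S²)
with S the *pooled within-group* covariance of z (clipped to [1/d, 1]);
ε_HF uses the between-groups-adjusted formula with the Lecoutre-corrected
numerator (N − g + 1), as in R's `car` package, capped at 1. Correction policy: HF if
ε_GG > 0.750, else GG; effects with one numerator df are never corrected.
η²p = SS_eff/(SS_eff + SS_err) per effect against its own error term.
Missing within-cells cause listwise deletion of the subject per analysis; a
cell empty for all subjects raises an error naming the cell. Degenerate
zero error variance yields F = ∞ (or NaN when the effect is also zero)
rather than a crash. Implementation is validated against a brute-force
cell-means oracle, the F = t² identity for 1-df effects, pingouin, and
(during development) R's `car::Anova`.

**Post-hocs.** All pairwise paired t-tests on participant marginal means,
collapsing other within factors by averaging (the collapsing scheme is a
documented choice; software differs here), Bonferroni-multiplied by the
number of comparisons.

**Analyses run by the pipeline**: gait speed and step length each as
2 × 3 × 3 Headset × Content × Modulation; crossing step length as
2 × 2 × 2 × 3 adding Location (initiation/halfway); static head pitch as
2 × 2 × 7 Headset × Content × Distance; walking head pitch per task as
2 × 3 × 3 (three content levels are retained for both the speed task — the
bird cue is what makes the content effect interesting — and the step task,
where sound-augmented footprints are a genuine third level).

## Numerical and design choices

* One value per participant × condition (the protocol runs each condition
  once); multiple repeats, if configured, are averaged before the ANOVA.
* Trial accounting distinguishes `analyzed`, `excluded` (hurdle trials,
  with reason), `calibration`, and `missing` (extraction failure, with the
  measurement's reason).
* The type-I calibration property is exercised at the statistics layer
  (null Gaussian parameter tables → ANOVA rejection rate), since the
  kinematic layers are deterministic pass-throughs for that question; the
  study-scale recovery property (n = 21, 100 seeds) runs the full
  simulate → detect → extract → test chain.
* Walkway coordinate is continuous, origin at the start line; internal
  units are meters/seconds, reported units cm, cm/s and degrees.

## Known limitations

* The generator's crossing-step geometry (fixed 15 cm margins) reproduces
  the *direction* of the published initiation-vs-halfway difference
  (halfway crossings longer), not its magnitude, which depends on where a
  walker's last regular step happens to fall before the obstacle.
* No mediolateral kinematics, hurdle-clearance height, gait variability or
  freezing metrics; vertical positions are schematic swing arcs.
* The ANOVA assumes a balanced within-design after listwise deletion and a
  single between factor; multilevel models and Mauchly's test are out of
  scope (sphericity is handled through ε directly).
* Whole-trial missingness (sensor dropouts) is represented by extraction
  failures, not by a dropout-process model.
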