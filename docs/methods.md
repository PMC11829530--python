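# Methods

This note documents the models, rules and numerical choices behind
`saccadekit`, and what its synthetic-data tests do and do not show
about real recordings.

## Geometry and coordinates

All internal positions are degrees of visual angle with screen-centre
origin, rightward/upward positive. Pixel↔degree conversion uses a
per-axis arctangent about the screen centre rather than a small-angle
linearisation; at the 8–10° eccentricities of the saccade tasks the
linearisation error would already exceed the gain tolerances of
interest. The default display is a 24″ 16:9 monitor (1920 × 1080)
viewed from 90 cm; physical size is derived from the diagonal and the
pixel aspect ratio when not measured. Binocular recordings are reduced
to one stream by averaging the eyes sample-wise where both are valid
and taking the valid eye otherwise; which single eye (or combination)
enters analysis is a convention, not an empirical claim, and the
reduction function is exposed so users can substitute their own.

## Event detection

Speed is the Euclidean norm of per-axis 5-point central differences at
the nominal 500 Hz; acceleration is the first difference of speed.
The 5-point stencil is the standard compromise between lag and noise at
this rate; it attenuates the peak of very short (< 25 ms) saccades,
which matters below (SWJ recovery). A saccade candidate opens when
speed exceeds 30 °/s **or** |acceleration| exceeds 8000 °/s², closes
when speed falls back under the velocity threshold, merges with a
neighbour closer than 2 samples, and is kept only if its net
displacement reaches 0.15°. These three thresholds are the fixed
parser configuration of the emulated acquisition setup and are exposed
in `DetectionParams`. Candidates within 50 ms of a blink (validity gap
> 20 ms) are discarded because eyelid motion mimics saccadic velocity.

Square-wave-jerk pairing takes consecutive saccades and requires
(a) both amplitudes in [0.1°, 5°]; (b) inter-saccadic interval
≤ 200 ms; (c) the first saccade moving gaze away from fixation and the
second within ±30° of antiparallel; (d) the second landing within 50%
of the outward amplitude of the fixation point ("refoveation"). The
verbal definition fixes (a) and (b); the ±30° and 50% tolerances are
our operationalisation of "opposite direction" and "refoveate", both
exposed as parameters. Pairing is greedy left-to-right and each
saccade joins at most one SWJ; the field's definition is silent on
triplets and overlaps, and greedy matching is the simplest rule that
guarantees a matching. The SWJ rate pools the three fixation trials
(total count over total analysed minutes); per-trial rates can be
computed by running `detect_swjs` per trial.

## Trial scoring

Reference events: target onset for pro/antisaccade trials, the go
signal (central-fixation offset) for memory-guided trials. The primary
saccade is the first detected saccade of amplitude ≥ 2° at or after the
reference; smaller saccades never enter analysis (the 2° floor also
applies to anticipation and inhibitory checks).

Exclusions, in precedence order: **blink** (a blink overlapping
[target onset − 100 ms, primary-saccade offset]); **fixation error**
(gaze outside a 2° radius of fixation for ≥ 100 ms during the
pre-target fixation interval); **amplitude threshold** (primary gain
> 2.0 or endpoint off-screen); **no saccade** (no qualifying primary).
The 2° radius and 100 ms dwell are our parameters — the exclusion
category is named in the emulated protocol without thresholds — as is
the gain-2.0 operationalisation of "exceeding the defined range of
motion". Two deliberate precedence choices: an anticipatory saccade
(≥ 2°, in the fixation period or within 80 ms of target onset)
classifies the trial as *anticipation* rather than excluding it as a
fixation error, since every anticipation necessarily leaves fixation
and anticipation is a reported outcome, not an artifact; likewise a
memory-guided saccade toward the target during the delay is the
*inhibitory error* outcome, so the fixation-error window for that task
ends at target onset.

Categories follow the task taxonomy: prosaccade error = primary
opposite the target; antisaccade correct = primary away from the
target with gain = amplitude/8 against the mirror location (reported
antisaccade gains near 1 imply mirror-target normalisation);
corrected error = a later ≥ 2° saccade crossing to the mirror side,
with correction latency measured from the erroneous saccade's onset
(the definition admits onset- or offset-anchoring; onset is the
default and the anchor is a parameter); memory-guided directional
error = post-go primary on the wrong side; correct memory-guided gain
= amplitude / eccentricity, binned 5° vs 10°. The memory-guided
response period is [go, go + 1000 ms] (length not specified by the
protocol; configurable).

Aggregation: error rates are category counts over *valid* (non-excluded)
trials — for memory-guided outcomes, over that eccentricity's valid
trials; kinematic outcomes are means over correct trials; a task with
zero valid trials yields missing values, never zeros. Whether the
anticipation-rate denominator should itself exclude anticipations is
ambiguous in the source taxonomy; we use all valid trials and note that
the alternative (non-anticipation valid trials) is a one-line change.
Participant QC flags anyone whose excluded-trial percentage on any task
exceeds the Tukey fence Q3 + 1.5·IQR (strict inequality).

## Group statistics

For each of the 23 outcomes (1 fixation + 5 prosaccade + 7 antisaccade
+ 10 memory-guided), the test is Welch's t if both groups pass
Shapiro–Wilk at α = 0.05, else Mann–Whitney U; outcomes with zero
variance in both groups are skipped (no test is defined) and drop out
of the Benjamini–Hochberg family, mirroring how degenerate outcomes are
handled in practice. The emulated protocol judged normality
graphically; Shapiro–Wilk is substituted for reproducibility, and the
choice is logged per outcome. Welch rather than pooled t because group
sizes are unequal and variance homogeneity is unverified. Effect sizes
are Cohen's d (pooled SD) for t and the rank-biserial correlation
rb = 2U₁/(n₁n₂) − 1 for U, both positive when the first (control)
group is larger. p-values for U are exact (full enumeration) for
tie-free samples with n ≤ 20 per group, otherwise the tie-corrected
normal approximation.

ANCOVA is the linear model outcome ~ group + covariate with the
type-II partial F for group. Exploratory Pearson correlations between
questionnaire scores (S-EDE-Q subscales/global, STAI state/trait, BMI)
and the outcomes carry no multiplicity correction, by design — they are
flagged exploratory. Mahalanobis screening compares squared distances
(sample mean/covariance) with the χ²(p) quantile at α = 0.001, the
conventional multivariate-outlier default; the cutoff is a parameter.
Group classification uses a pooled-covariance linear discriminant with
leave-one-out accuracy.

**Power.** The a-priori per-group n for a two-sided two-sample t-test
is the smallest integer whose noncentral-t power reaches the target
(d = 0.80, α = 0.05, power = 0.80 → n = 26/group). Pearson-test power
offers three methods: `nct` (default) — the noncentral-t
"point-biserial" routine used by the standard power calculators, with
noncentrality ρ√n/√(1−ρ²), which reproduces their printed numbers
(0.621 at ρ = 0.3, n = 54); `exact` — integration of the exact sampling
density of r under a bivariate normal (0.607 at the same
specification, confirmed by Monte Carlo); and `fisher_z` (0.599). The
three differ by a percentage point at this n; the default is chosen
for comparability with the conventional tooling, and the exact method
is the reference implementation for the sampling distribution itself.

## The synthetic-data generator

The simulator emulates the acquisition conditions the pipeline
assumes: 500 Hz monocular-reduced traces; the 60/40/40/40/60
pro/antisaccade block design at ±8°; 52 memory-guided trials, 13 per
(side × {5°, 10°}) cell, 50 ms flash, 1000–3000 ms delays; three
one-minute fixation trials. Saccades have raised-cosine velocity
profiles scaled to the main sequence v_peak = v_max(1 − e^(−A/A₀))
with v_max = 500 °/s, A₀ = 5° — a smooth symmetric stand-in chosen
because the detector needs realistic kinematics, not a mechanistic
waveform. Each task trial realises exactly one sampled category; the
defaults (anticipation 0.55; prosaccade error 0.003; antisaccade
uncorrected 0.17, corrected 0.15; memory-guided inhibitory 0.02,
directional 0.011; latency medians 317/440/690 ms for pro/anti/
memory-guided; gain 0.98 ± 0.055; exclusion probabilities ~4.4%/1.4%/
0.2% for pro-anti and 1.6%/5.6%/0.5% for memory-guided) follow the
scale reported for healthy young-adult cohorts on this battery.
Latency *shapes* (lognormal, σ = 0.2) are stand-ins — the emulated
protocol reports only means and SDs. Memory-guided response latencies
are truncated at 920 ms so simulated compliant participants respond
within the 1000 ms response period. SWJ counts per fixation trial are
Poisson at the configured rate, placed with ≥ 1 s separation;
amplitudes U(0.3°, 1.5°), return = outward ± N(0, 0.05°), intervals
U(50, 180) ms. Blinks are 100–300 ms validity gaps.

Position noise is band-limited Gaussian — white noise convolved with a
~30 ms Hann kernel, rescaled to the configured marginal SD (default
0.05°). This models video-oculography precision, which is dominated by
tremor/drift and low-passed sensor noise; white per-sample noise of the
same amplitude would put ~24 °/s of velocity noise and ~2·10⁴ °/s² of
acceleration noise on every sample, and no fixed-threshold parser
could run on such a signal.

A separate outcome-level sampler draws participant outcome rows
directly (normals for kinematic outcomes at the battery's scale;
binomial counts over realistic trial numbers for rates, which
reproduces zero-variance outcomes such as rare inhibitory errors).
It is used for calibration studies of the comparison stage where
trace-level simulation adds nothing.

**What passing tests show.** Recovery tests demonstrate that the
pipeline is consistent: injected rates, categories and exclusion
probabilities are recovered within Monte-Carlo error under the
generator's assumptions. They do not validate the detector against
human data — real saccades have asymmetric velocity profiles, glissades
and post-saccadic oscillations; real noise is heteroscedastic; real
participants drift, fatigue and re-calibrate. The generator
deliberately omits smooth pursuit, vergence, pupil dynamics and
learning effects across blocks.

## Numerical notes and known limitations

- Detector onsets lag injected onsets by the threshold-crossing time
  (~4–6 ms at these kinematics); latency tolerances in tests budget
  for this. Event endpoints extend one sample beyond the
  threshold-crossing run.
- Saccades below ~0.35° are intrinsically undetectable under the fixed
  thresholds: the main-sequence peak velocity at 0.3° is 29 °/s
  (below the 30 °/s threshold) and peak acceleration ~4400 °/s²
  (below 8000). With SWJ amplitudes U(0.3°, 1.5°) the pair-detection
  rate is ~0.92 overall (1.00 above 0.7°), so a 4/min injected rate is
  recovered at ~3.6–3.7/min. This is a property of the thresholds, not
  of the implementation.
- Null calibration of the comparison stage is assessed as the mean
  per-outcome rejection rate pooled over outcomes and cohorts; at 200
  cohorts a single outcome's binomial noise (SD ≈ 0.015) would
  otherwise dominate the check.
- The simulated-cohort scale used in tests (20 participants for SWJ
  recovery, 10,000 trials for category recovery, 200 null cohorts) was
  chosen so each recovery's Monte-Carlo error sits well inside the
  tolerance being asserted.
- Degenerate inputs: zero-variance outcomes are skipped, not tested;
  empty task cells yield missing outcomes; the Mahalanobis screen
  refuses singular covariances; ties disable the exact U-test path.
- The boxplot QC fence uses linear-interpolation quartiles
  (numpy default); other quartile conventions move the fence slightly.
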