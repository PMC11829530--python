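# saccadekit

Oculomotor event detection, saccade-task scoring and two-group
digital-biomarker statistics for 500 Hz gaze recordings.

`saccadekit` implements, as a tested and reusable pipeline, the analysis
used in eye-tracking studies of oculomotor digital biomarkers: fixation
stability (square-wave-jerk rate), the five-block prosaccade/antisaccade
paradigm, and memory-guided saccades, followed by participant-level
quality control and a normality-guided two-group comparison with false
discovery rate control. It is aimed at researchers who record gaze with
a video eye tracker (or want ground-truthed synthetic recordings) and
need the full chain from raw samples to a group-comparison table.

## What it computes

**Events.** Saccades are segmented from the speed series (5-point
central difference at 500 Hz) with the standard parser thresholds:
velocity 30 °/s, acceleration 8000 °/s², motion 0.15°. Blinks are
validity gaps > 20 ms. Square-wave jerks (SWJs) are consecutive saccade
pairs — an outward saccade then an approximately antiparallel return
that refoveates fixation — within 200 ms, both amplitudes in
[0.1°, 5°]; the fixation-task outcome is the SWJ rate per minute.

**Trial scores.** Each pro/antisaccade and memory-guided trial is
excluded (blink, fixation error, amplitude threshold) or classified:
anticipation (saccade in the fixation period or latency < 80 ms),
prosaccade error, antisaccade corrected/uncorrected error, memory-guided
inhibitory or directional error, else correct with

- gain = first-saccade amplitude / desired amplitude (8° for
  pro/antisaccade, 5° or 10° for memory-guided),
- latency = first-saccade onset − reference (target onset, or the go
  signal for memory-guided trials),
- peak velocity (°/s).

Saccades under 2° are never analysed; error rates are proportions of
valid trials.

**Statistics.** The 23-outcome family (1 fixation + 5 prosaccade +
7 antisaccade + 10 memory-guided measures) is compared between groups
with Welch's t or Mann–Whitney U (chosen per outcome by Shapiro–Wilk at
α = 0.05), Benjamini–Hochberg adjustment across the family, Cohen's d /
rank-biserial effect sizes, ANCOVA with a covariate, exploratory Pearson
correlations against questionnaire scores, a Mahalanobis multivariate
outlier screen, linear-discriminant group classification, and power
calculations (a-priori two-sample t sample size; Pearson-test power by
the noncentral-t, exact-r-distribution or Fisher-z method).

**Synthetic cohorts.** A first-class simulator generates the full task
battery as 500 Hz traces with main-sequence saccades
(v<sub>peak</sub> = v<sub>max</sub>(1 − e<sup>−A/A₀</sup>), raised-cosine
velocity profile), Poisson SWJ pairs, blinks, band-limited position
noise and per-trial ground-truth categories, so every pipeline stage is
testable without human data.

## Worked example

```
$ saccadekit power --d 0.8 --alpha 0.05 --power 0.8
26
$ saccadekit power --rho 0.3 --n 54
0.6210
```

26 is the minimum per-group sample size for a two-sided two-sample
t-test to reach 80% power at a large effect (d = 0.80, α = 0.05);
0.6210 is the power of a two-sided Pearson correlation test to detect
ρ = 0.3 with 54 participants at α = 0.05 — about 62%, i.e.
underpowered for small correlations.

A full synthetic pipeline run:

```
$ saccadekit simulate --out-dir cohort --n-control 2 --n-subclinical 2 --seed 5
$ saccadekit score --in-dir cohort --out outcomes.tsv
$ saccadekit analyze --outcomes outcomes.tsv --out comparison.tsv
saccadekit: wrote comparison.tsv (23 outcomes)
```

`comparison.tsv` has one row per outcome with group means/SDs, the test
chosen, its statistic, raw and BH-adjusted p, and the effect size.
Identical config and seed give byte-identical outputs.

The same chain from Python:

```python
import saccadekit as sk
from saccadekit.simulate import CohortConfig, simulate_cohort
from saccadekit.pipeline import outcomes_table

recordings, truth = simulate_cohort(CohortConfig(n_control=4, n_subclinical=4, seed=1))
rows = outcomes_table(recordings)
for r in sk.compare_groups(rows)[:3]:
    print(r.outcome_name, r.test, round(r.p_raw, 3))
```

## Layout

| module | contents |
| --- | --- |
| `saccadekit.geometry` | screen geometry, pixel↔degree conversion, gaze/trial/participant types |
| `saccadekit.simulate` | schedules, ground-truthed trial/cohort simulation, outcome-level sampler |
| `saccadekit.events`   | saccade/blink detection, SWJ pairing, SWJ rate |
| `saccadekit.scoring`  | exclusions, per-task trial classification, outcome aggregation, boxplot QC |
| `saccadekit.stats`    | group comparisons, BH, ANCOVA, correlations, Mahalanobis, LDA, power |
| `saccadekit.io` / `saccadekit.cli` | gaze CSV + annotations JSON formats, result TSVs, YAML config, CLI |

See `docs/methods.md` for the underlying model, parameter defaults and
known limitations.
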