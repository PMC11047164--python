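# Methods

This note documents the models, detection rules, statistical procedures and
numerical choices implemented in `swayn1`, and what the synthetic cohort
does and does not establish.

## Analysis chain

### Center-of-pressure biomechanics

The anterior–posterior (AP) COP position (cm, 100 Hz) is differentiated
with a three-point central difference — interior sample *i* receives
`(x[i+1] − x[i−1])·fs/2`, exact for quadratics and free of phase delay;
endpoints get one-sided first differences so the series keeps its length
(the rule itself says nothing about endpoints; one-sided differences are
the smallest-assumption choice).

Per subject, anterior and posterior foot limits define a rectangular
stability zone with the origin at the initial COP reference.  The distance
to boundary (DTB) at each sample is taken toward the boundary the COP is
currently moving at (anterior limit when COPv > 0, posterior when
COPv < 0, the nearer boundary at exactly zero — a measure-zero case).  The
time to boundary is

```
TTB = min( DTB / max(|COPv|, ε), cap )
```

with ε = 0.6 cm/s and cap = 10 s by default.  ε is treated as a
posturographic noise floor: below roughly the quiet-stance median speed the
*direction and magnitude* of differentiated COP are dominated by
measurement noise, and the raw ratio DTB/|COPv| degenerates into a
deterministic hyperbola of the velocity estimate.  With ε comparable to the
typical quiet speed, near-stationary samples saturate (at `DTB/ε` or the
cap) and TTB carries genuine boundary-proximity information rather than a
re-expression of COPv; this is what gives the four features the moderate
(|r| < 0.7) correlation structure a combined model needs.  Both constants
are configuration fields.

Instability events are local extrema of |COPv| (strictly greater than the
preceding sample, not less than the following one, so plateaus yield their
first sample; both polarities accepted) exceeding a per-subject threshold of
3·SD of COPv over the first 20-s quiet-stance (gain 0) trial.  Each peak is
paired with the first subsequent sample where COPv changes sign (product of
consecutive samples ≤ 0, no sub-sample interpolation; 10-ms resolution is
ample for 100–250 ms windows).  Peaks within a 500-ms refractory period of
an accepted peak, and peaks with no subsequent sign change, are dropped.
The threshold multiplier is exposed in configuration because per-subject
adjustment conventions vary.

### N1 detection and epoching

The cleaned fronto-central EEG independent component (IC, 100 Hz) is
baseline-corrected by subtracting its pre-task (−5..0 s) mean; the SD of
that window defines the per-subject depth unit.  For each instability
event, the N1 is the most negative local minimum lying at or below −2
baseline SD within −250..−100 ms before the event's zero-crossing (ties go
to the earliest; plateaus to their first sample; no smoothing).  Events
with no qualifying trough are discarded rather than widened.  All other
local minima at or below −2 SD form control candidates, excluding: troughs
within ±300 ms of any N1, troughs inside the detected event span
(−2.45..+1.35 s around zero-crossings, so drift/corrective-phase activity
cannot enter the control class — an exclusion policy this package chooses
explicitly and exposes in configuration), troughs whose −300..+100 ms epoch
would leave the recording, and troughs closer than 400 ms to a deeper
retained trough (greedy, deepest first).

Epochs span −300..+100 ms around each center with every channel at its
native rate (41 samples at 100 Hz; whatever 10-Hz samples fall inside the
closed window).  Alignment across rates is unnecessary because the feature
stage uses per-window medians only.

### Features and descriptive statistics

Each epoch reduces to the median of absolute values of COPv, SH, HA and TTB
over −300..−50 ms before the center (the window ends at −50 ms — on the
order of vestibular afferent latencies — so only pre-response signal is
used; the start is configurable between −350 and −250 ms).  The median is
the default summary for robustness; the mean is available by option and
gives similar results.  Class contrasts report group means ± SE, pooled-SD
Cohen's d, and Welch two-sample t-tests — Welch because the classes have
unequal sizes, which makes exact pairing impossible.  The correlation
screen reports Shapiro–Wilk p per feature and the six pairwise Pearson
coefficients, flagging |r| ≥ 0.7 as collinear.

### Classification protocol

For each left-out subject and repeat (default 10 repeats × 10 subjects):
the subject's epochs are balanced by undersampling their majority class
(test set); the remaining subjects' pooled epochs are balanced the same way
(training set); a stratified 5-fold grid search over XGBoost
hyperparameters (depths {2,4,6,8,10}, estimators {60,100,140,180,220},
learning rates {0.001,0.01,0.1} — a discretization of the protocol's
printed ranges; a reduced {2,4}×{60}×{0.1} grid serves desk-scale runs)
selects the best mean validation accuracy, ties resolved toward the
simplest model (smaller depth, then fewer estimators, then smaller learning
rate); the winner is refit on the full balanced pool and scored on the test
set.  Balanced test sets put chance at 50%.  Metrics: accuracy at the 0.5
probability threshold, sensitivity for the instability class, and the
rank-based (Mann–Whitney, tie-corrected) AUC.

Undersampling and permutation streams derive from (master seed, subject,
repeat) only, so all feature sets see identical subsets; the model seed
additionally folds in the feature set.  A label-permutation mode shuffles
the classes per run before any balancing — the chance-level control.

Feature importance uses exact TreeSHAP attributions computed by the fitted
booster itself (per-sample contributions that sum with the base value to
the margin output, to float32 precision).  Global importance per run is
summarized on the balanced *training* pool — the data the ensemble actually
explains — because rankings computed on a single left-out subject's small
test set are dominated by per-subject sampling noise.  The direction
summary is the sign of the correlation between feature values and their
attributions.  Model comparisons run all ten pairwise independent t-tests
per metric across run-level values at a significance level of 0.005.

## The synthetic cohort

No human recordings are distributed, so a seeded generator emulates the
study design: ten subjects, nine consecutive 20-s sway-referenced trials
(gains 0, 0.4, 2.0, 0, 0.6, −0.4, 0, 1.0, −1.0), a 5-s pre-task baseline on
the IC trace, COP at 100 Hz, shear at 10 Hz, head acceleration generated at
80 Hz and decimated to 10 Hz through the same anti-aliased resampler the
instrumentation path requires.

**Sway.**  COP velocity is an Ornstein–Uhlenbeck process (relaxation 40 ms,
quiet-stance SD 0.5 cm/s, scaled by `1 + 0.1·|gain|` per trial — the
gain→variance map is unconstrained by any published statistic and is chosen
weak so trial condition does not dominate epoch features), integrated with
a slow positional leak (80 s) that keeps the COP near its reference.  A
saturating sub-0.015-Hz lean (SD 0.6 cm, bounded at ±1.5 cm, anchored at
zero at task onset) adds realistic slow postural wander.  A hard clamp at
99% of the limits guarantees the COP never exits the stability zone (no
falls).

**Instability events.**  Events arrive as a renewal process (mean rate
0.19 /s, 3.5-s dead time so excursions never overlap; ~34 events per
subject).  Each event is a four-phase velocity waveform time-locked to its
corrective zero-crossing: a smooth sin² *approach* bump (1 s, amplitude
scaled per event so the excursion's deepest point comes within ~2.1 cm of
the boundary the subject is heading for, capped at 2 cm displacement to
stay below the detection threshold); a *drift* ramp-and-plateau
(0.65 cm/s, ending 120 ms before the crossing) — the phase the pre-response
feature window observes; a half-sine *spike* (peak 10 cm/s, 120 ms), the
supra-threshold peak the detector keys on; and a *corrective* reversal
(1.2 s; quarter-sine attack over 80 ms so the zero-crossing slope stays
steep against background sway, then a slow release) whose area cancels the
accumulated displacement.  Events head toward the boundary the subject is
leaning to (random when centered), reversing only when the excursion would
otherwise reach the wall.  This "precarious approach" construction is what
makes boundary proximity — not raw speed — the class signature, so TTB is
the most discriminative feature by design, which is the regime the analysis
targets.

**EEG component.**  The IC background is 1/f noise band-passed 1–20 Hz,
normalized to unit SD, attenuated to 0.7× during the task (task-related
desynchronization of the resting background) with a 1-s ramp.  Each event
receives an inverted-Gaussian N1 trough (amplitude 3 baseline SD, FWHM
80 ms) at a latency drawn from Normal(165 ms, 10 ms), clipped to
105–245 ms, before its zero-crossing.  Distractor troughs (depth
Normal(3, 0.3) SD, same width) are injected at Poisson times (2.2 /s)
outside event footprints and at least 0.5 s apart; together with
spontaneous deep minima of the background they yield roughly two control
epochs per instability epoch (pooled instability proportion ≈ 0.35–0.37
across seeds, matching the study scale of ~32%).

**Coupled channels.**  Shear force and head acceleration are noisy linear
functions of low-pass-filtered COPv (0.5 Hz and 0.6 Hz cutoffs; gains 1.2
N/(cm/s) and 0.15 (m/s²)/(cm/s); white noise 0.4 N and 0.4 m/s² at the
native rates).  The low-pass reflects the physics — shear tracks whole-body
inertia and the head moves more slowly still — and is what keeps these
channels moderately, not collinearly, correlated with COPv.

**Determinism.**  Every draw flows from one per-subject stream spawned as
`SeedSequence(cohort_seed, spawn_key=(subject_index,))`; identical
parameters give bit-identical recordings.  Ground truth (event
zero-crossings, N1 times, distractor times) is recorded for recovery
scoring.

**Calibrated structure (cohort seeds 42/1/7).**  Effect sizes d ≈ 1.3–1.6
(COPv), 1.6–2.0 (SH), 0.45–0.6 (HA), 2.2–3.1 (|TTB|); all pairwise
correlations |r| ≤ 0.68; control:instability ≈ 1.7; event recall 1.00 with
mean zero-crossing error < 10 ms and false events < 0.005 /s; N1 recall
0.98 with mean latency 166.9 ms; the combined model ranks TTB first by mean
|SHAP| in ≥ 95% of runs; label permutation returns 49–51% accuracy.

**What the generator does not emulate.**  Real EEG nonstationarity,
artifacts, and inter-subject variation in N1 morphology; mediolateral
dynamics; the continuous spectrum of real instabilities (events here are a
stereotyped waveform family); physiological coupling beyond first-order
linear-plus-noise channel models; absolute classification performance —
the synthetic classes are more separable than real ones, so accuracy
magnitudes here (≈0.9 for the combined model) exceed what human data
yield and should not be compared numerically.  Passing tests establish that
the *pipeline* recovers what was injected and that the comparative
structure (which feature dominates, chance behavior, protocol integrity)
behaves correctly — not that real cohorts would produce these numbers.

## Problem sizes

Default analyses use the 10-subject, 180-s cohort (≈900 epochs).  Repeated
LOSO evaluations in the test suite and the acceptance script use the
reduced hyperparameter grid with 10 repeats per subject (100 runs per
feature set), which reproduces the protocol's comparative structure at a
few seconds per feature set.

## Known limitations

* The velocity floor ε interacts with the cap: for quiet standing far from
  the boundary most TTB samples saturate, which is intended (safe samples
  are "effectively unbounded") but means TTB distributions are mixed
  discrete/continuous; medians, not means, should summarize them.
* Events with no qualifying N1 trough are dropped rather than re-windowed;
  with the default generator this affects < 3% of events.
* The per-subject COPv threshold uses the first trial including any events
  that fall in it, as the protocol's quiet-stance rule prescribes; cohorts
  with much higher event rates would inflate the threshold.
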