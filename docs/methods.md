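# Methods

`nirsmat` implements a complete analysis chain for prefrontal-cortex
fNIRS recordings acquired during a mental-arithmetic task (MAT), aimed
at separating healthy controls (HC) from chronic-migraine (CM) and
medication-overuse-headache (MOH) patients.  Because no public dataset
of this kind exists, the package ships a synthetic-cohort generator
with the statistical structure the analysis assumes; the generator is
first-class, tested code, and every downstream stage is exercised
against it.

## Task protocol

The MAT is a three-stage block protocol: 60 s eyes-closed rest, a task
stage of 45 back-to-back arithmetic cycles (1 s question, 4 s
countdown, 1 s answer, 1 s feedback — 7 s per cycle, 315 s total), and
180 s eyes-closed recovery; 555 s in all.  Stage boundaries are
half-open intervals, and segmentation converts them to sample indices
by rounding `duration × sampling_rate`.  All durations must be
strictly positive.

## Synthetic recordings

Each subject is a four-channel HbO/HHb recording at 17 Hz (the
nominal rate of the four-optode PFC headgear montage F7/Fp1/Fp2/F8;
ch2 ≙ Fp1 and ch3 ≙ Fp2 are the analysis channels).  The forward
model is

    HbO(t) = baseline + A · (h ⊛ s)(t) + noise(t)
    HHb(t) = baseline_hhb − κ · A · (h ⊛ s)(t) + noise'(t)

where `h` is a canonical double-gamma hemodynamic response (positive
gamma peaking at 6 s — inside the 5–8 s latency window reported for
optical responses to stimulation — minus a 1/6-amplitude undershoot
peaking at 16 s, peak-normalized), `s` is an impulse train with one
event per arithmetic cycle, `A` is a group×channel amplitude with
subject-level Gaussian jitter (sd 0.1 a.u.), and `κ = 0.3` is the
neurovascular coupling ratio that makes HHb anti-correlated with HbO —
required so that HbT = HbO + HHb and COE = HHb − HbO carry distinct
information.  Noise is the sum of sinusoids with random phase at the
cardiac (1.0 Hz), respiratory (0.3 Hz) and Mayer-wave (0.1 Hz) bands
(amplitudes 0.3/0.2/0.2 a.u.), a random quadratic drift (0.3 a.u.
coefficients) and white Gaussian noise (0.15 a.u.).  The frequency
assignment is the physiological one: heartbeat ~1 Hz, respiration
~0.3 Hz, Mayer waves ~0.1 Hz.

Group structure, all in arbitrary concentration units:

* evoked HbO amplitude at ch3 (right PFC): HC 0.3 vs CM/MOH 1.0 —
  migraineurs respond to task stress with a larger right-PFC
  blood-volume increase, the effect the stage-1 classifier exploits;
* cycle-to-cycle response jitter (multiplicative sd on per-cycle
  impulse weights): HC 0.10, CM 0.12, MOH 0.60 — cycles are 7 s apart
  (≈ 0.14 Hz), so this jitter lands inside the band-pass branch and
  drives the task-stage HbO/HbT standard deviation that separates MOH
  from CM;
* a sustained COE transient at ch2 after task onset (saturating
  exponential, τ = 10 s): gain HC 0.05, CM 0.10, MOH 0.60 — drives
  the normalized COE task-onset slope;
* for MOH subjects the two subject-level factors above are coupled
  through a correlated lognormal pair (default correlation 0.9),
  reproducing the band-shaped association between COE onset slope and
  task variability that distinguishes MOH scatter from CM scatter.

Group effect sizes are free parameters of the generator; the defaults
were chosen once so that the full pipeline recovers the labels of a
34-subject cohort at ≥ 80 % leave-one-out accuracy, giving a cohort
that is neither trivially separable nor hopeless.  They are not
estimates of any clinical effect magnitude.

Ages are drawn per group from normal distributions (HC 44.9 ± 8.7,
CM 34.8 ± 10.9, MOH 45.8 ± 11.2 years) truncated to the 20–60
recruitment window and feed only the age-correlation diagnostic.
Subject seeds are `cohort_seed + a stable per-group offset`, so
enlarging one group never perturbs previously generated subjects.
Identical `(params, seed)` give bit-identical cohorts, including after
a CSV round-trip.

What the generator does **not** emulate: raw optical intensities and
the Beer–Lambert conversion, motion artifacts, scalp/systemic
interference differences between channels, non-stationary noise, and
any real covariance between clinical status and physiology beyond the
three planted effects.  Passing tests therefore demonstrate that the
pipeline is correct and can recover group structure of the planted
kind at realistic cohort sizes and noise levels — not that the
classification generalizes to clinical recordings.

## Preprocessing

Two Butterworth filters run in parallel on each analysis channel:
a 4th-order low-pass at 0.1 Hz (slow task-level trend; removes
cardiac/respiratory/Mayer oscillations) and a 4th-order band-pass at
0.01–0.3 Hz (per-stimulus response band; the band-pass order is not
independently specified anywhere, so it matches the low-pass order).
Both are applied forward and backward (zero-phase) so stage boundaries
are not delayed by group delay; the effective magnitude response is
the squared Butterworth response.  Edge handling is reflective
("even") padding of 10 s.  Zero-phase filtering of a finite record
necessarily leaves an edge transient: for an additive sinusoid it is
about 13 % of the sinusoid's amplitude at the first/last samples and
decays over roughly the filter settle time, while interior suppression
is better than 1e-4.  Features that include the record boundaries
(rest and recovery means, and especially the min–max range used by
normalized features) inherit a corresponding small sensitivity; the
property tests quantify this (raw low-pass features are stable to 1 %
of the contaminant amplitude, normalized ones to ~10 %).

From each filtered pair, HbT = HbO + HHb (blood-volume proxy) and
COE = HHb − HbO are derived.  The COE sign convention is fixed so that
an oxygenation decrease raises COE.  Filtering and derivation are both
linear, so their order is interchangeable (checked to 1e-9).

## Features

For each of the 4 signals × 2 channels (ch2, ch3), 18 features:

* low-pass branch, raw (6): the three pairwise stage-mean differences
  (`A_B_mean_d` = mean(A) − mean(B); task−rest, recovery−rest,
  task−recovery), the two transition slopes (OLS slope over the first
  8 s after the task onset, `TB_slope`, and after the recovery onset,
  `RB_slope` — the 8 s window covers the 5–8 s response latency), and
  their difference `slope_d` = TB − RB;
* the same six recomputed on the min–max-normalized signal (suffix
  "(01)"), where normalization uses the full-record min/max of that
  branch signal, so "(01)" features measure change relative to the
  subject's own signal amplitude;
* band-pass branch (6): population standard deviation, skewness
  (m₃/m₂^{3/2}) and Pearson non-excess kurtosis (m₄/m₂², Gaussian → 3)
  of the task and recovery stages.  Moments use 1/n weighting.

8 × 18 = 144 features, named e.g. `HbT_task_rest_mean_d (01, ch3)`,
in a deterministic signal-major, channel-minor order.  Band-pass
distribution statistics are computed for the task and recovery stages
only: including the rest stage would give 168 features and is
inconsistent with the 144-column design this feature set is built to,
and no rest-stage distribution feature appears in any analysis scheme.
Extraction fails fast (naming the feature) on any non-finite value —
notably a constant signal, whose min–max normalization is undefined.

The optional age diagnostic z-scores a feature and reports its Pearson
correlation with age, guarding against the group-age confound (CM
subjects are ~10 years younger on average).

## Classification

LDA and QDA are implemented from the Gaussian class model: class c is
N(μ_c, Σ_c) with prior π_c and discriminant

δ_c(x) = −½ log|Σ_c| − ½ (x−μ_c)ᵀ Σ_c⁻¹ (x−μ_c) + log π_c,

with Σ_c the class-size-weighted pooled covariance for LDA.
Covariances use 1/n_c weighting; each is regularized as
Σ + λ·(trace(Σ)/p)·I with λ = 1e-6 by default, keeping two-feature
fits invertible at class sizes as small as six.  Ties break to the
earlier class in the declaration order HC < CM < MOH.  scikit-learn's
discriminant classes serve only as an independent cross-check in the
test suite.

Splitting is stratified 2:1 per class with round-half-up train counts,
which reproduces 34 → 23/11 for class sizes (13, 9, 12) and 21 → 14/7
for (9, 12).  Model credibility on small cohorts is assessed by
leave-one-out cross-validation; a fold whose removal empties a class
trains on the remaining classes when at least two survive.

Two schemes:

* **direct** — one three-class QDA on
  `HbT_recovery_rest_mean_d (ch3)` + `COE_recovery_skewness (ch3)`;
* **stepwise** — stage 1 separates HC from CM ∪ MOH by QDA on
  `HbT_task_recovery_mean_d (ch3)` + `HbT_task_rest_mean_d (01, ch3)`;
  stage 2 separates CM from MOH among migraineurs on either
  `HbO_task_std (ch3)` + `COE_TB_slope (01, ch2)` (set 1) or
  `HbT_task_std (ch3)` + `COE_TB_slope (01, ch2)` (set 2).

The headline stepwise 3×3 confusion matrix composes leave-one-out
predictions with **predicted-label routing** — subjects predicted
migrainous at stage 1 are passed to a stage-2 model trained on the
other migraine subjects — since that is what a deployed two-stage
classifier does.  True-label routing (stage 2 applied only to true
migraineurs) is reported alongside.  Stage-wise train/test/LOOCV
accuracies use the stratified splits above; stage 2 trains on migraine
subjects only.

The feature pairs above were fixed by exhaustive wrapper search:
`search_feature_pairs` scores all C(144,2) = 10,296 pairs by LOOCV
accuracy (deterministic; ties broken lexicographically).  On a
34-subject table the full scan takes about a minute.

## Numerical and design notes

* Determinism: every stochastic component is driven by
  `numpy.random.default_rng` seeds derived from a single cohort seed;
  identical configuration ⇒ byte-identical artifacts.
* Recording CSV uses `%.17g` formatting and round-trip float parsing,
  so write → read → write is byte-identical.
* Degenerate inputs fail loudly: constant series (normalization,
  skewness/kurtosis), singular covariances at zero shrinkage (error
  advises shrinkage), classes with fewer than two members, stage
  windows past the record end, mismatched series lengths.
* Problem sizes in the test and acceptance runs mirror the study
  design: 34-subject cohorts (13/9/12), 555 s records at 17 Hz;
  property tests that need tighter sampling bounds use 20–50 subjects
  per group.

## Known limitations

* The generator's effect structure is planted, low-dimensional and
  stationary; accuracy figures on synthetic cohorts characterize the
  pipeline, not clinical performance.
* The direct scheme's features were chosen for the original clinical
  cohort; on the synthetic cohort the generator plants no
  recovery-stage skewness effect, so direct LOOCV accuracy sits well
  below the stepwise scheme's — the orderings, not the values, are
  the meaningful comparison.
* Min–max normalization is edge-sensitive under zero-phase filtering
  (see Preprocessing); a trimmed-range variant would be more robust
  but would change the "(01)" feature definition.
* LOOCV on 34 subjects has a binomial standard error of ~7 percentage
  points; single-run accuracies should be read accordingly.
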