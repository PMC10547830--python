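# Methods

This note documents the models and procedures implemented in `eegleak`,
the parameter choices that matter, and what the synthetic experiments do
and do not show.

## Synthetic cohort model

No generative description of the original clinical EEG exists, so the
generator is designed around the two statistical properties that the
leakage phenomenon actually requires, and nothing else:

1. **Subject fingerprints.** Each subject's signal is a 1/f-shaped
   broadband background plus band-limited Gaussian oscillations in the
   conventional EEG bands (delta 1–4, theta 4–8, alpha 8–12,
   beta 13–30 Hz) plus white sensor noise. The per-band, per-channel
   log-power offsets are drawn once per subject from
   `N(0, fingerprint_strength²)` and held fixed for the whole epoch.
   Because the signal is stationary within the epoch, any two crops of
   one recording share the subject's spectral profile — this is the
   mutual predictiveness that trial-wise CV exploits.
2. **Group effect.** Patients receive a shift of
   `effect_size × fingerprint_strength` in target-band log power
   (default 8–12 Hz) on a fixed quarter of the channels, chosen
   reproducibly from the cohort seed. The shift is expressed in units of
   the between-subject log-power standard deviation, so `effect_size`
   reads as a standardized (Cohen's d) group difference; the realized
   per-channel d on generated cohorts tracks the configured value to
   within a few percent (verified in the test suite). Note the
   standardization scale is the fingerprint spread itself: with
   `fingerprint_strength = 0` there is no between-subject variability to
   standardize against and the effect vanishes — a deliberate
   degeneracy, since such a cohort has no subject identity to leak
   either.

Default amplitudes (delta 2.0, theta 1.5, alpha 2.0, beta 1.0 RMS units,
background 1.0, `noise_sd` 0.5) keep the oscillations dominant over the
in-band noise floor, so log-power shifts remain approximately additive.
They are plausible relative magnitudes for eyes-closed resting EEG, not
fits to any dataset. Everything is a pure function of `CohortSpec.seed`
(per-subject seeds are spawned from it), so cohorts are bit-reproducible.

**What the generator does not model:** eye blinks, muscle artifacts,
non-stationary drifts, volume-conduction correlation structure between
channels, or clinical covariates. Consequently, passing tests show that
the *pipeline arithmetic and the leakage mechanism* behave as claimed;
they do not certify absolute accuracy levels on real EEG.

## Cropping and trial counts

Crops start at `0, step, 2·step, …` with `step = w·(1 − overlap)`;
the count per epoch is `⌊(T − w)/step⌋ + 1`. For 60-s epochs this gives
6 trials per subject at 10 s non-overlapped and 21 at 10 s with 75%
overlap, and cohort totals of 135/405/540/810/1620 trials for the
60/20/15/10/5-s windows (135 subjects, non-overlap) and 1215 at 20 s
with 75% overlap. Published tallies of overlapped counts are not fully
self-consistent across sources; this closed-form convention is the one
the package implements and tests. Downsampling (1000 → 200 Hz in the
reference pipeline) uses polyphase FIR resampling, which low-pass
filters below the new Nyquist before decimation.

## Cross-validation plans

All four schemes use repeated, label-stratified k-fold assignment
(default 10 repetitions × 10 folds). Stratification is applied even
though the reference protocol does not state it: with a 77/58 imbalance,
unstratified folds only add variance to balanced accuracy. Subject
grouping stratifies subjects; trial grouping stratifies trials. Each
repetition draws its shuffle from a sub-seed spawned from
`(plan seed, repetition)`, so repetitions are independent but
individually reproducible, and plans serialize to JSON for exact reruns.
Every plan carries a per-fold **contamination** figure — the fraction of
test trials whose subject also has a trial in training — and the audit
treats any contaminated subject-grouped fold as a hard failure. With a
60-s window each subject contributes one trial, all four schemes
coincide, and the plan is tagged `degenerate_equal`.

## Classifiers

PyTorch-free by design: the two CNNs run on a small numpy layer
framework (`eegleak._nn`) with sliding-window convolutions contracted
through BLAS, reverse-mode gradients (verified against brute-force
references in the tests) and an Adam optimizer.

- **Compact CNN** (EEGNet-style): temporal convolution (kernel = fs/2,
  no bias) → batch-norm → depthwise spatial convolution across all
  electrodes (D=2) → batch-norm → ELU → average-pool 4 → dropout →
  separable convolution (depthwise temporal kernel 16 + pointwise) →
  batch-norm → ELU → average-pool 8 → dropout → dense. At the published
  filter counts (F1=8, D=2, F2=16) the flattened last-convolutional
  output on a 10-s, 200 Hz input is `16 × ⌊⌊2000/4⌋/8⌋ = 992`
  dimensions — the anchor that fixes the architecture. Defaults:
  lr 1e-3, dropout 0.5.
- **Deep CNN** (CNN-13-style): 5 temporal convolutions (kernel 5, EEG
  channels enter as input feature maps) each followed by max-pool 2,
  then 3 fully-connected layers; leaky-ReLU, dropout 0.1, lr 1e-4. The
  layer composition (5 conv + 5 pool + 3 FC) is fixed; exact filter
  counts are an implementation choice (paper scale 16–256, desk scale
  4–16), so the model is a "CNN-13-style" classifier, not a bit-level
  reproduction of any published network.
- **Spectral baseline**: per-channel log band power in 2-Hz sub-bands
  (1 Hz to min(40, Nyquist), Welch), standardized, classified by
  logistic regression (C=100). The fine sub-band resolution is
  deliberate: it gives the linear model enough capacity to memorise
  subject fingerprints, so it exhibits the same leakage behaviour as the
  CNNs at a tiny fraction of the cost and carries the fast experimental
  grids. Its band-power matrix doubles as its "penultimate features".

Shared training protocol: per-trial, per-channel z-scoring at model
input, batch size 5, cross-entropy, Adam, no early stopping, no
validation split, no class weighting (imbalance is handled only in the
metric). `scale="paper"` uses 300 epochs and full filter counts;
`scale="desk"` (the test default) uses 30 epochs and halved filters so a
fold trains in seconds on one CPU. Training is deterministic given
`(data, config.seed)` on one machine; across BLAS builds, hard labels
may differ in rare near-tie cases, which is why quantitative tests
assert margins rather than exact accuracies.

## Voting and scoring

A subject's diagnosis is the class winning at least 60% of its
test-trial votes. The threshold is inclusive (`≥ 0.6`): the reference
description says "more than 60%" but its own worked example classifies a
subject on exactly 3 of 5 votes, so the example is taken as normative.
If neither class reaches the threshold the subject abstains and is
counted as misclassified (abstention rates are reported separately).
Trial-grouped schemes are scored per trial, without voting. Accuracy is
balanced accuracy in percent; a repetition pools its k folds (each unit
tested exactly once), and a grid cell reports mean ± SD over
repetitions — the aggregation granularity is a package choice, as the
reference protocol leaves it unstated.

A subtlety worth recording: under a null effect, subject-wise accuracy
with voting is *not* centred on 50% in general. If a null model's
trial votes are independent coins, the subject-correct probability is
`P(Binom(m, ½) ≥ ⌈0.6 m⌉)` (≈ 0.34 for m = 6) because abstentions count
as errors; if the votes are fully coherent (the typical regime when
subjects have fingerprints) it is ½. `evaluate.null_accuracy_band`
therefore spans both extremes when the tests check that honest CV stays
at chance.

## Scheme statistics

Per (model, window): Friedman omnibus across schemes over the
per-repetition accuracies, then all pairwise Wilcoxon tests with
Bonferroni correction (family = pairs within the window). The reference
analysis names the rank-sum test for its paired post-hocs; both the
two-sample rank-sum (default, following that text) and the paired
signed-rank variant are provided. A fully tied table short-circuits to
statistic 0, p = 1.

## Feature-space view

Penultimate features of all trials in a fold are embedded to 2D with
t-SNE (Euclidean distance, perplexity `min(30, (n−1)/3)`, seeded), and a
two-class LDA boundary is fitted **on training rows only** in the plot
space. When the pooled covariance is singular the discriminant falls
back to an explicitly ridge-regularized solve, which degrades gracefully
to the class-mean direction. Caveat: the t-SNE map itself is fitted on
train and test rows jointly, as the figure of record does; that is a
mild transductive leak, acceptable for a visual diagnostic but the
reason no performance claim is derived from the embedding.

## Problem sizes used in the shipped tests

The quantitative acceptance properties run on reduced cohorts chosen so
the full suite completes in minutes on one CPU: 40+40 subjects, 8
channels, 60-s epochs at 100 Hz with the spectral baseline for the
leakage-inflation and pure-leakage-null properties (3×10-fold CV), and
12+12 subjects, 4 channels, 30-s epochs at 64 Hz for the all-family
honest-null guard. At these sizes the leakage inflation is large
(tCV − sCV ≳ 15 percentage points) and stable across generator seeds;
the effect only grows at the full reference scale.

## Known limitations

- Absolute accuracies from the reference clinical study are not
  reproducible here: those data are not public, and the synthetic
  cohorts are deliberately minimal.
- The deep CNN's exact layer parameters are an implementation choice
  (see above).
- Stationary fingerprints are a simplification; real EEG fingerprints
  drift, which can only weaken trial-wise leakage relative to this
  worst(-honest)-case model, not create it.
- EDF interchange is not implemented; the cohort container is HDF5.
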