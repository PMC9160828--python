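# Methods

## Problem and model

The package addresses a small-cohort clinical prediction problem: given a
patient's resting-state EEG, predict whether a course of repetitive
transcranial magnetic stimulation (rTMS) will improve their cognition.
Response is defined from the Mini-Mental State Examination: a subject whose
MMSE does not decrease after treatment is a responder (TMS+), one whose MMSE
decreases is a non-responder (TMS-); a constant score counts as benefit.
The study conditions the package emulates are 14 subjects (8 responders, 6
non-responders), ~30 scalp channels in the 10-20 montage, 500 Hz sampling,
4-minute eyes-closed recordings.

The feature representation is the *windowed band-power series*: each channel
is band-limited to the five canonical EEG rhythms — delta 0.5-4, theta 4-7,
alpha 7.5-13, beta 15-28, gamma 29-48 Hz (the gaps between printed edges are
excluded, not closed) — by zeroing FFT bins outside the band and inverse
transforming; the filtered signal's mean squared amplitude is then averaged
in consecutive non-overlapping 2-s windows. This keeps a time course of
power per (channel, band) rather than collapsing each band to one scalar,
preserving the multi-source structure of the montage: transforms never cross
a channel boundary, and a provenance index maps every flattened feature back
to its (channel, band, window).

The classifier is a soft-margin SVM with Gaussian kernel
K(x, x') = exp(-||x - x'||² / 2σ²), decision function
f(x) = Σ_m α_m y_m K(x, x_m) + b. σ denotes the kernel *width* (not the
inverse-width γ); unset, it resolves to σ = sqrt(d·Var[X]/2), which keeps
the kernel scale commensurate with the feature dimension d. A stepwise
linear discriminant (SWLDA) is provided both as an alternative linear
classifier and as a feature selector.

## Validation engine

Accuracy is estimated by balanced Monte-Carlo leave-one-out: each subject is
held out once; from the remaining 13, a maximal class-balanced subset (six
per class, or five when a minority-class subject is held out) is drawn
repeatedly and split into a balanced training set and a balanced validation
set (one subject per class in validation by default). The trial count per
fold is the combinatorial count of distinct maximal balanced subsets,
C(max, max−min), times the count of balanced train/validation partitions,
capped at 50. Drawing a maximal balanced subset directly (uniformly without
replacement per class) is distributionally equivalent to drawing many random
selections and keeping a maximal balanced one, so the engine does the former.

Everything that learns — standardization statistics (z-score by training
mean/SD), feature selectors, hyperparameters, the classifier — is fit on the
training rows of each trial only. The final model is fit on the training set
alone; the validation set exists to drive hyperparameter selection when the
search is enabled. Every split plan is checked for pairwise disjointness and
exact class balance at construction; a violation aborts the run rather than
biasing it. Folds that cannot be balanced are reported as skipped, never
silently dropped from denominators.

Direct classification (no validation set) uses class-stratified random
train/test splits at a 9/14 training fraction over 50 trials, reporting the
mean and SD of test accuracy.

## Feature-selection routes

All selectors operate on standardized features and are re-fit inside every
trial (leakage-safe per-fold fitting; this is stricter than fitting once
globally, and deliberately so):

* **none** — the full windowed power-spectra vector (~18,000 features).
* **pca** — top-k principal components of the training covariance
  (default k = 20, clipped to n_train − 1; with 12 training subjects the
  projection rank is at most 11).
* **wavelet** — per-channel Daubechies-4 decomposition at the maximum level
  the block length permits, symmetric boundary extension; coefficients
  ranked by mean |value| over training rows, global top 10% kept; blocks
  shorter than the filter support are zero-padded and flagged.
* **swlda** — forward inclusion by smallest partial-F p-value below
  α_in = 0.10, backward elimination above α_out = 0.15 (the standard
  stepwise convention in the BCI literature), capped at the number of
  training samples; an empty selection is a flagged warning state that
  predicts the majority class, not an exception.
* **band_restrict** — keep one band's features via the provenance index
  (theta by default, the band that carries the class signal).

Feature importances are read as cumulative per-band |w| from a *linear*-
kernel SVM fit on the same standardized training data: primal weights
w = Σ α_m y_m x_m are undefined under the RBF kernel, so the ranking model
is a linear companion while the RBF model remains the classifier.

## Hyperparameter search

The (C, σ) search is an interval-shrinking coarse-to-fine procedure on a
log10 scale: evaluate a coarse grid (5 points per axis over C ∈ [1e-2, 1e3],
σ ∈ [1e-2, 1e2]), re-center the interval on the best point, halve interval
and step, and stop at the first iteration that fails to improve the best
accuracy (at most 6 iterations, final step ~1.5% of the initial width).
Ties break toward smaller C, then smaller σ — the simpler model —
deterministically. Exhaustive grid search is retained as an optional mode
and as the oracle the evolutionary mode is tested against. The search is
off by default in the engine (C = 1, σ = scale heuristic); when enabled it
maximizes validation accuracy per trial.

## Synthetic cohorts

The generator emulates the study conditions with known ground truth. Each
channel is: pink (1/f-shaped) Gaussian background with total SD 17 µV, plus
one unit-variance band-limited Gaussian component per canonical band scaled
by gain × 5 µV, plus a shared broadband source mixed with random per-channel
weights (U(0.2, 0.8) × 5 µV) so the montage has non-trivial spatial
correlation. Band components are built by FFT masking of white noise — the
same band definition the feature extractor uses — so band confinement is
exact. With unit gains the theta-band SNR against the pink background is
near 1, and total signal SD (~20 µV) keeps essentially all epochs under the
±100 µV rejection threshold. The responder class carries a theta amplitude
gain of 1.5 by default (a 2.25× theta power ratio); identical gains make the
classes exchangeable by construction, which is the null control.

MMSE scores are drawn as integers in [10, 28] (a plausible mild-to-moderate
dementia range); responders gain 1-3 points, non-responders lose 1-3, and by
default a quarter of responders keep a constant score to exercise the
tie-goes-to-responder rule. Per-subject seeds are spawned from the master
seed by counter-offset spawn keys, so cohorts regenerate bit-identically and
per-subject.

What the generator does *not* emulate: realistic forward-modeled scalp
topographies, eye-blink/EMG artifacts, nonstationarity, volume-conduction
structure beyond the single shared source, or inter-subject variability in
spectral shape. Passing the recovery tests therefore shows the pipeline
finds a band-localized power effect of the stated size under these idealized
conditions; it does not certify performance on clinical recordings.

## Preprocessing

Zero-phase (forward-backward) IIR filtering: Butterworth order 4 band-pass
0.1-60 Hz plus a second-order 50 Hz notch with Q = 30. Recordings are cut
into 1-s epochs; any epoch whose peak absolute amplitude exceeds ±100 µV on
any channel is rejected — a deterministic, reproducible stand-in for manual
epoch review and ICA blink correction, which cannot be replicated in
software. Features are computed on the concatenation of kept epochs; an
optional strict mode breaks windows at rejected-segment boundaries instead.
Non-scalp channels (reference, ground, EOG) are excluded by label at read
time.

## Numerical choices

* Feature-extraction window length defaults to 2 s (1 s and 4 s are
  supported for the window-size comparison); 2 s is the documented optimum
  of that comparison.
* Band power is computed in the time domain after FFT-mask filtering; the
  frequency-domain band-bin sum is kept as the test oracle (the two agree by
  Parseval to 1e-6 relative).
* SVM solver tolerance is 1e-6, at which the libsvm dual matches a
  high-precision QP solve to ~1e-6 in α; decision ties (f = 0) break toward
  the majority training class and are recorded.
* Degenerate inputs: zero-variance features standardize to zero (guarded
  divide); an all-rejected epoch set and a single-class training set raise
  explicit errors; an empty stepwise selection falls back to the majority
  class with a flag.
* Subjects may retain different clean-epoch counts after rejection; feature
  matrices are truncated to the cohort-wide minimum window count before
  stacking.

## Problem sizes used in the automated runs

The test suite's end-to-end checks run ten cohorts per condition at the full
study conditions (14 subjects, 30 channels, 500 Hz, 240 s). The acceptance
script (`scripts/acceptance.py`) runs five cohorts per condition, each
through the complete engine (up to 50 trials per fold, 14 folds), which the
package treats as its standard reporting configuration; unit tests use
smaller cohorts (7 subjects, 6 channels, 30 s) chosen to exercise every code
path quickly.

## Known limitations

* With 14 subjects, leave-one-out accuracy has high variance; the
  Monte-Carlo averaging reduces trial noise but not subject-level noise.
* The chance band used for the null control is the exact Binomial(n, 1/2)
  band over fold outcomes — the maximum-variance envelope of the engine's
  correlated trial outcomes — so the null check is conservative.
* The SWLDA route inherits the classical instability of stepwise selection
  at n ≪ p; it is included as a comparison route, not a recommendation.
* EDF/EDF+ and BrainVision recordings are read via MNE; on-disk export of
  synthetic cohorts is BrainVision only.
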