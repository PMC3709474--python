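# Methods

This note documents the models, conventions and numerical choices behind
`bolddecode`, in the order data flows through the package.

## Synthetic BOLD data

**Design.** A run holds `n_per_condition_per_run` events of each
condition (default: 8 × 4 conditions = 32 events), in pseudo-random order
with at most `max_consecutive_same` (default 2) consecutive events of one
condition. Inter-stimulus intervals, and the lead-in before the first
event, are drawn independently and uniformly from
`[isi_min, isi_max]` = [10, 19] s. The sequence constraint is enforced by
rejection sampling of balanced permutations (200 retries) with a
largest-remaining-count greedy scheduler as a constructive fallback; an
exhaustive scan in the test suite confirms that no generated sequence
violates the constraint. Default acquisition: TR = 3 s, 4 runs,
210 volumes/run — 630 s comfortably holds the worst-case event span
(32 × 19 s) plus a six-volume extraction tail.

**Hemodynamic response.** A double-gamma impulse response
`h(t) = g(t; 6, 1) − (1/6) · g(t; 16, 1)` (gamma densities; shape, scale),
rescaled so its maximum is 1. It is causal (`h(t) = 0` for `t ≤ 0`),
peaks at ≈ 5 s, undershoots and returns below 10⁻³ of peak by 40 s. All
parameters are configurable through `HrfParams`.

**Signal model.** Each (ROI, condition) pair has a voxel-amplitude map;
by default a random half of the ROI voxels (`pattern_sparsity = 0.5`)
carry standard-normal amplitudes, and the maps of different conditions
are drawn independently — distinguishable in expectation, spatially
interleaved, with no mean-amplitude difference between conditions. A
voxel's time series is the superposition of `effect_size × amplitude ×
h(t − onset)` over events, sampled at volume start times `k·TR`, plus a
per-run linear drift (slope SD `drift_slope_sd = 0.01` signal units per
volume) and white Gaussian noise (`white_sd = 1`). With unit noise,
`effect_size = 1` yields clearly decodable but imperfect single-subject
accuracies, and `effect_size = 0` is an exact null. Runs use independent
random streams derived from one seed; identical seeds give bit-identical
datasets.

**What the simulator does not emulate:** spatial autocorrelation of the
noise, physiological (cardiac/respiratory) fluctuations, scanner
artefacts, subject motion, and between-region signal leakage. Passing
tests therefore demonstrate the correctness and calibration of the
*analysis machinery* under the stated noise model, not expected effect
sizes on real data.

**Control ROI.** Voxels sampled uniformly without replacement from
outside the brain mask, matched in count to the rounded mean of the ROI
sizes. By construction these voxels contain drift and noise but no
stimulus signal.

## Preprocessing

Per run and voxel, the least-squares linear trend (intercept + slope) is
removed, then (default) the voxel's run time series is z-scored. One
volume per event is extracted: volume `k ≥ 1` is the k-th complete volume
beginning after the onset (`containment` convention; a `ceil` variant
counts an exactly-aligned volume as the first), `k = 0` is the volume
whose acquisition window contains the onset. With TR = 3 s and onsets
falling mid-volume, `k = 2` samples 4–6 s post-onset — the HRF peak — and
is the default. Trials whose extraction volume falls outside the run are
dropped with a logged warning, never imputed. Finally each trial pattern
is standardized across voxels (mean 0, SD 1). This last step is what
makes decoding provably insensitive to uniform amplitude rescaling of
any condition (asserted exactly in the tests); both normalization steps
can be toggled independently.

## Decoding

Binary tasks use scikit-learn's `SVC(kernel="linear")` — the libsvm
soft-margin SVM — with fixed `C = 1` (configurable; the suite checks the
key properties for C ∈ {0.1, 1, 10}). Cross-validation is
leave-one-run-out: every run is the test set exactly once, and the task's
accuracy is the unweighted mean of fold accuracies. Multiclass decoding
trains one classifier per condition pair and tallies the six votes per
test trial; the modal label wins. Ties are broken uniformly at random
from the pipeline's seeded generator (default) or deterministically by
condition order (`lowest-index`), and the voting logic is verified
against an exhaustive 2⁶-pattern enumeration. No statistic is ever
estimated across the train/test boundary: run-wise normalization is
label-blind and confined to single runs, and trial standardization is
per-trial.

## Inference

**Permutation test.** Condition labels are shuffled *within subject and
within run* — preserving run-level exchangeability under
leave-one-run-out — and the full cross-validated decoding is recomputed
per permutation; the group mean of the permuted accuracies forms one
null draw. The default shuffles training and test labels alike
(`both`); a `train-only` mode shuffles only the labels the classifiers
learn from. With the counting convention `p = #(null ≥ observed)/n`, a
zero count is reported as the upper bound `< 1/n`; a conservative
`(count+1)/(n+1)` convention is available. The permutation loop uses an
internal fast path (identical SVC fits, manual `w·x + b` evaluation, no
result-object construction) that the suite verifies to be exactly equal
to the public decoding path.

**Paired comparisons.** Task-set contrasts (e.g. pertinent vs
non-pertinent tasks, where a task is pertinent to an ROI if it involves
one of the ROI's principal modalities) use the Wilcoxon signed-rank test:
zero differences dropped, exact distribution up to 25 informative pairs,
normal approximation beyond. All-zero differences (e.g. ceiling
accuracies in strong-signal simulations) carry no information; the
workflow reports them as NaN rather than failing.

**Saliency control.** Spearman's rho (midranks for ties) between
per-task saliency-rating differences and accuracies, with a two-sided
permutation p-value under the same reporting convention.

## Maps

Subject sensitivity maps average the four fold weight vectors of a
task's classifiers (the combination across folds is a package choice;
any monotone combination of fold weights would serve). The group map is
the per-voxel one-sample F = t² against zero with df (1, n−1); 14
subjects give the α = 0.05 threshold F > 4.67. Voxels that are zero in
every subject are undefined (NaN, excluded); nonzero-mean voxels with
zero between-subject variance get a +inf sentinel — both warned. Map
dissimilarity is 1 − Pearson r over voxels finite in both maps (zero
weights are informative and retained). The univariate GLM uses
HRF-convolved condition regressors plus per-run intercept and linear
drift, solved by ordinary least squares with an explicit rank check that
names collinear columns.

## Problem sizes used in the validation suite

The chance-calibration runs (and `scripts/acceptance.py`) use 50
replicate null groups of 6 subjects at the full design and acquisition
defaults, but on a compact single-ROI grid (8×8×6 voxels, 4×4×4 ROI):
the null has no spatial structure, so geometry only sets the voxel
count. Type-I-error calibration of the permutation test uses 200 null
studies of 2 subjects × 2 runs × 8 trials/run × 16 voxels at 1,000
permutations — the smallest layout with genuine leave-one-run-out
structure. Signal-recovery checks use 20 seeds of 4-subject groups at
the default `effect_size = 1`; the accuracy time-course sweep uses
`effect_size = 0.6` so the profile stays off ceiling and the peak volume
is identifiable. The `ci` workflow profile (6 subjects, 1,000
permutations) mirrors these scales; the `paper` profile (14 subjects,
10,000 permutations) reproduces the full-scale analysis settings.

## Known limitations

- Subject-to-common-space registration is out of scope: group maps
  assume all subjects share one voxel grid (the simulator guarantees
  this; real-data users must supply pre-registered maps).
- The spatial statistics of real non-principal response patterns
  (sparsity, amplitude distribution) are unknown; the simulator defaults
  are plausible placeholders, not estimates, and are exposed for sweeps.
- No motion correction, smoothing or physiological-noise modelling;
  motion parameters are accepted only as a table for per-condition
  reporting.
- The four-way tie-break rule and the exact onset-to-volume convention
  of historical analyses are not recoverable; both are documented,
  configurable choices here.
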