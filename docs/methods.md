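# Methods

This note documents the models, defaults and numerical choices behind
`voxelstab`, and what the synthetic benchmarks do and do not establish.

## Signal model of the synthetic generators

The generators produce beta-value feature matrices directly (the raw BOLD
stage is separate, see below). The signal model is a class-conditional
mean shift on the informative voxels:

* binary (sentence/picture-style): informative voxels get −e/2 for class 0
  and +e/2 for class 1, where `effect_size` e is expressed in units of
  `noise_sd`;
* 8-category (object-vision-style): the informative voxels are divided
  round-robin into one cluster per category, and a sample of category c
  adds `effect_size` to its category's voxels only (category-selective
  tuning).

Noise is i.i.d. Gaussian on the betas. Informative voxels are placed by
drawing ball-shaped clusters of `cluster_radius` (grid units) around
random centers until the quota is filled; radius 0 disables clustering.
Because voxels are a random subset of the grid, a "ball" can be sparse —
clustering is a tendency, not a guarantee of contiguity.

What this emulates: the dimensionality, trial structure, class balance
(including the one-dropped-trial case), and the existence of a compact
informative subpopulation. What it does not emulate: temporal
autocorrelation, physiological/motion artifacts, spatial noise
correlation, inter-subject variability, and realistic effect-size
distributions. Passing results on these benchmarks demonstrate that the
machinery is correct and that selectors behave as theory predicts under a
clean planted signal; they do not predict absolute accuracy or stability
levels on real acquisitions.

Defaults mirror the benchmark structure: 40 trials × 2 samples with ~2000
candidate voxels (16×16×8 grid) for the binary design; 12 trials × 8
categories = 96 samples with 675 voxels (15×15×3) for the multi-category
design. Default `effect_size = noise_sd = 1` (a 1σ contrast) is a
moderate regime in which selectors are challenged but not hopeless; tests
and the reproduction script state their own effect sizes explicitly.

## Raw BOLD stage and the beta-series GLM

`simulate_bold` renders per-event amplitudes into scanner time series:
each voxel is a sum over events of amplitude × (stimulus boxcar ⊛
canonical double-gamma HRF, peak 6 s, undershoot 16 s, ratio 1/6, unit
peak) sampled at TR, plus Gaussian noise. Regressors are built at 16×
temporal oversampling; a zero-duration event is a unit impulse, so its
regressor is the HRF itself.

`glm_features` inverts this with a beta-series (one-regressor-per-event,
least-squares-all) GLM: per-voxel OLS against the event regressors plus
an intercept and an optional linear drift. The per-event parameterisation
is chosen because the feature matrix needs one row per presented sample.
Rank is checked by pivoted QR before fitting and rank deficiency is an
error naming the offending columns — no silent regularisation. No
prewhitening or autocorrelation correction is applied; with white
simulated noise OLS is efficient, and on real data this module would be a
plain (not generalized) least-squares estimate.

## Selectors

All five selectors share one contract: (subsample, labels, validation
pair) → selected index set. Multiclass problems are handled one-vs-rest
throughout. All ranking ties break toward the smallest feature index, so
every selector is a pure function of its inputs.

* **Correlation**: |Pearson r| between each voxel and the ±1 class
  coding; multiclass takes the max over one-vs-rest codings; constant
  features score 0.
* **Mutual information**: each voxel is discretized into `mi_bins = 8`
  equal-frequency bins (rank-based: ordinal ranks divided into equal
  blocks, which is deterministic under ties), then plug-in MI in bits
  from the joint contingency table. Equal-frequency binning is the robust
  choice at these sample sizes; `mi_bins > n` is an error rather than a
  silent clamp, so the subsample size bounds the usable bin count.
* **SVM-RFE**: backward elimination removing
  `max(1, floor(0.1 × surviving))` features per round by |w| of a linear
  SVM (sum over one-vs-rest machines), never overshooting below k. The
  exact libsvm solver is used for each round's fit.
* **LASSO / elastic net**: L1 (resp. mixed) penalized logistic
  regression on internally standardized features. The penalty strength λ
  is searched on a 30-point log grid from the data-dependent maximum
  (KKT bound `max_j |x_jᵀ(y − ȳ)|/n`, divided by the L1 fraction for
  mixed penalties) down to 10⁻³ of it; the grid is traversed from
  sparse to dense and the validation-accuracy maximiser wins, ties
  keeping the larger λ (sparser model). The support is every coefficient
  with |w| > 10⁻⁸ (solvers rarely return exact zeros), unioned over
  one-vs-rest machines.

The elastic-net mixing weight `alpha` multiplies the **ridge** term —
`penalty = (1−α)Σ|w| + αΣw²` — so `alpha = 0` reduces exactly to the
LASSO and the default `alpha = 0.8` is a strongly grouped regime. This is
the reverse of the scikit-learn/glmnet `l1_ratio` convention; internally
`l1_ratio = 1 − alpha`, and the documentation states the mapping because
silently porting an `l1_ratio` value would invert the intended mixing.

Solver routing: pure-L1 paths use liblinear (exact coordinate descent)
with `intercept_scaling = 100` so the intercept is effectively
unpenalized, matching the convention in which only feature weights are
shrunk; mixed penalties use saga with warm starts along the λ path
(tol 10⁻⁴), whose proximal step yields exact zeros. Because `alpha = 0`
routes through the identical code path as the LASSO, the reduction
identity holds exactly rather than up to solver tolerance.

Filter/wrapper subset sizes, when not fixed, are tuned on the validation
set over a log-spaced ladder (1, 2, 5, 10, 20, 50, … capped at m), ties
to the smallest size. The benchmarks never state their size grids; the
ladder spans the plausible range at every scale.

## Stability selection

The resampling plan defaults to 50 subsamples of half the training set,
drawn without replacement and stratified by class (largest-remainder
rounding of the per-class quotas) — unstratified half-sampling of small
per-class counts too easily produces degenerate training sets. Each
iteration derives its RNG from (master seed, iteration index), so runs
are reproducible and iterations independent of execution order.

Embedded methods re-tune λ on the validation set inside every resampling
iteration — the literal reading of the protocol in which validation
controls the tuning parameters during selection. Filter/wrapper methods
tune k once per replication (before the loop): the final subset is the
top-k of the frequency profile, which requires a single k per
replication anyway.

Thresholding uses ≥ Θ (so Θ = 1.0 is attainable). If no voxel reaches Θ
the single most frequent voxel is kept and the selection is flagged as a
fallback — a downstream classifier needs at least one feature, and the
flag keeps the event visible in reports.

Stability of k subsets is the mean Jaccard index over all k(k−1)/2
unordered pairs. Two empty sets have undefined similarity and raise
rather than silently scoring 0 or 1.

## Cross-validation and evaluation

* Sample-level scheme: per replication, disjoint class-stratified
  train/test/validation sets of sizes (60, 10, 10) from 80 samples, 10
  replications from independent seed substreams. Replications' test sets
  are independent random draws, not a partition.
* Trial-level scheme: one replication per trial (12, or 11 with a
  dropped trial); the held-out trial is the test set and the remaining
  trials split 6 training / 5 validation. The validation block absorbs
  any remainder so the three blocks always partition the samples.

Final classifiers follow the selector pairing: linear SVM (C = 1, the
conventional default) for the correlation/MI/RFE tracks, regularized
logistic regression for the embedded tracks. The embedded refit needs a
λ; it is re-tuned on the full training set against the validation set,
since the per-iteration λs belong to subsamples half that size. The
reported stability is the mean pairwise Jaccard over the replications'
*final* subsets; accuracy STD is the sample standard deviation (ddof 1).
`theta_sweep` computes each replication's frequency profile once and
re-thresholds it per Θ, so the selector cost is independent of how many
thresholds are examined.

## Numerical choices and degenerate inputs

* OLS via LAPACK least squares; agreement with the pseudo-inverse is
  tested to 10⁻¹⁰ relative.
* Coefficient support threshold 10⁻⁸; correlation scores clipped to 1 to
  absorb rounding.
* Standardization guards zero-variance columns (scale forced to 1).
* Single-class labels, empty grids, out-of-range k/Θ, both-empty set
  pairs, and selector failures inside the resampling loop (reported with
  the failing iteration index) are all hard errors, never silent
  degradations.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses 40 independent datasets of 200 voxels with
10 planted informative voxels at 3σ and n = 80 samples for the recovery
measurement, and a 100-voxel / 5-informative dataset over the full
10-replication scheme for the benchmark rows — sizes at which the full
50-resample protocol runs comfortably on a laptop-class machine while
leaving the planted-signal regime representative.

## Known limitations

* The GLM stage assumes non-overlapping (or weakly overlapping) event
  regressors; rapid designs with short SOAs can be rank-deficient at the
  scan resolution, which is reported as an error rather than worked
  around with regularisation.
* Real-data idiosyncrasies (autocorrelated noise, anatomical ROI masks,
  inter-subject anatomy) are out of scope; absolute benchmark numbers on
  synthetic data should not be read as predictions for real datasets.
* With heavy ties (many identical feature values) rank-based
  equal-frequency binning splits tied values across bins, which can
  overstate MI for quantized features.
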