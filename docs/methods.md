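# Methods

This note documents the statistical machinery implemented in `rfshift`, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Regression trees

Trees are grown by exhaustive binary splitting on the deviance criterion:
for every candidate variable and every midpoint between consecutive
distinct values, the reduction

    SS(parent) − SS(left) − SS(right)

is evaluated (SS = sum of squared deviations of the outcome within the
node) and the strictly largest reduction wins. Ties are broken by lowest
column index, then smallest threshold, making growth fully deterministic
given the data and the per-node variable draw. A node is eligible for
splitting only while it holds at least `min_node_size` observations
(default 5) and its outcome values are not all equal; children may be
smaller than the minimum. Routing is "value ≤ threshold goes left",
including values exactly at the threshold. There are no surrogate splits:
designs are complete-case upstream, and prediction on a missing value
raises an error.

Standalone trees can be pruned by weakest-link cost-complexity pruning:
the internal node with the smallest deviance-gain-per-leaf-removed is
collapsed repeatedly, yielding the nested path of optimal subtrees indexed
by the complexity penalty α. Selection of α is left to the caller; a
K-fold cross-validation helper with an optional 1-SE rule is provided.
Trees inside forests are never pruned.

Numerical notes: node SS is computed in centred form; the split scan uses
prefix sums with child SS clamped at zero, so tiny negative values from
cancellation cannot manufacture splits; exactly-constant outcomes are
detected by min == max, not by an SS threshold.

## Random forests

A forest fits `n_trees` unpruned trees, each on a bootstrap sample of n
rows drawn with replacement, with a fresh uniform draw of `mtry` candidate
variables at every node. Predictions are the unweighted mean over trees.
Defaults: `n_trees = 500` and `mtry = max(1, ⌊p/3⌋)`, the conventions of
the classical R implementation of random forests for regression; both are
exposed parameters and echoed in every run manifest.

Out-of-bag (OOB) machinery: rows absent from a tree's bootstrap are its
OOB set (expected fraction (1 − 1/n)ⁿ → e⁻¹ ≈ 0.368). The per-tree OOB
MSE is each tree's error on its own OOB rows; the ensemble OOB MSE
predicts every row by averaging only trees for which it is OOB. Variance
explained is 1 − ensemble OOB MSE / Var(y) with the population
(divide-by-n) variance; it can be negative for uninformative predictors.
Trees whose bootstrap covered every row (possible at tiny n) are kept but
flagged and excluded from OOB averages.

Randomness: one master seed spawns independent substreams for the
bootstrap matrix and the per-tree node-level variable draws, so a fit is
bit-reproducible and independent of execution order.

## Permutation importance and the AVI

A variable's importance in one forest is the mean over trees of the
relative performance decrease when the variable is permuted within the
tree's OOB sample:

    d(k, j) = (MSE_perm(k, j) − MSE_oob(k)) / MSE_oob(k)

One fresh permutation is drawn per (tree, variable). "Relative" is
interpreted as normalization by the tree's own OOB MSE, which makes the
measure invariant to rescaling the outcome; a raw (unnormalized) mode is
provided for cross-checking against unscaled importances from reference
implementations. Trees with empty OOB sets, or zero OOB MSE in relative
mode, are excluded from the mean. Negative values are reported as-is —
clipping would bias trajectories near zero.

The AVI is the arithmetic mean (with SD) of the per-forest importances
over K independently seeded forest fits of the same design, K = 300 by
default. Stabilization is deliberately delegated to this averaging rather
than to multiple permutations within a forest. One-hot encoded covariate
columns additionally report an aggregated per-original-variable importance
(sum of member columns); the headline QoL predictors are numeric and
unaffected.

A known caveat of permutation importance — possible bias when predictors
differ strongly in scale or category count — is inherited, not corrected;
the composites and scales compared here share a common construction.

## Detection pipeline

Patients are split at 24 months into *worsened* (EDSS increase ≥ 1.0 from
a baseline < 5.5, or ≥ 0.5 from a baseline ≥ 5.5) and *not-worsened* (all
other classifiable patients). The half-point rule is applied at a baseline
of exactly 5.5 and, as a documented extension, above 7.0. Patients missing
either EDSS are unclassifiable and excluded. The not-worsened group is the
control arm, assumed free of response shift; it can be overridden only
explicitly.

For each group and model (M1: PCS, MCS + covariates; M2: the eight SF-36
scales + covariates) the AVI is computed at every visit, giving per-
variable trajectories plus per-visit variance explained. The same master
seed drives each visit's K runs — visits differ by their data, so nothing
is gained by separate streams, and a time-constant cohort then yields an
exactly flat trajectory. Crossing detection works on the piecewise-linear
interpolant of the five AVI points: with D(t) the pair's AVI difference, a
crossing exists on (t, t+1) iff D(t)·D(t+1) < 0, at time
t + D(t)/(D(t) − D(t+1)). Exact ties D(t) = 0 are "touches", reported but
not counted — near-zero AVI noise should not inflate detections. The
reprioritization flag is raised iff the worsened trajectories cross and
the control trajectories do not. Per-visit AVI ratios are reported at the
exact visits (no smoothing).

The optional matched analysis draws `n_per_group` worsened patients in
seed-randomized order and greedily pairs each with the nearest unused
control by baseline EDSS (ties broken by the seed-determined control
order) — a deterministic, seed-reproducible stand-in for the matched
sub-study design.

## Synthetic cohort generator

The generator targets the regression structure the forests see, not the
questionnaires themselves. Per patient:

* **Covariates** follow the published cohort marginals: age ~ N(41.3,
  10.2²) truncated at 18; 72.2% female; education 19.5% elementary /
  14.0% college / 66.5% high-school-university; 67.8% cohabiting/married;
  57.8% employed; disease duration ~ N(10.0, 7.5²) truncated at 0.
* **EDSS**: baseline ~ N(2.9, 1.9²) truncated to [0, 7.5], rounded to the
  half-point grid. The 24-month change is drawn group-conditionally so the
  disability classifier reproduces the intended label *exactly* (worsened:
  the clinically meaningful increment plus occasional extra steps;
  not-worsened: flat, −0.5, or just below threshold); intermediate visits
  interpolate on the grid. Infeasible draws trigger bounded resampling,
  then an error. With the default 107 worsened / 417 not-worsened split,
  ~20% of patients worsen, as published.
* **Domain scores**: a latent 8-vector (clusters PF, RP, BP, GH physical;
  vitality, SF, RE, MH mental) follows a stationary AR(1) across visits
  (ρ = 0.7) with multivariate-normal innovations; correlations default to
  0.5 within cluster and 0.25 between (assumptions recorded in the truth
  file — the real structure is unreported). Scores are mapped to 0–100 as
  `72 + 15·z` minus a modest disability penalty (2.5 points per EDSS step
  on physical domains, 1.0 on mental) and clipped; clipping at 100 mimics
  the ceiling effects typical of SF-36 scales.
* **Composites**: PCS and MCS are norm-based T-scores of the
  cluster-mean standardized scores — the linear map is calibrated on the
  generated cohort's *baseline* sample (no external norm population exists
  for synthetic data), so baseline PCS/MCS have mean 50 and SD 10 by
  construction of the norm, at any cohort size.
* **Global index**: domain scores are standardized by their baseline
  moments, combined with the group's visit-specific weights (normalized to
  sum to 1), scaled by `index_gain = 18`, shifted to 50, noised with
  `noise_sd = 8` index points, and clipped to [0, 100]. These two values
  were set so the true signal-to-total variance ratio of the index model
  is ≈ 0.69, consistent with the 55–71% variance explained reported for
  such models; the forests recover 0.5–0.65 on cohorts of a few hundred.
* **Scenarios**: the control scenario keeps a constant mental > physical
  cluster-weight contrast (0.3) in both groups. The reprioritization
  scenario lets the worsened group's contrast fall linearly from
  `0.3 + strength` at M0 through zero exactly at the requested crossing
  visit t*, reversing afterwards, while the control arm stays constant;
  `strength = 0` means no reprioritization and returns the control
  configuration. Default strength 0.5. An MCAR missingness injector
  (default off) exercises the complete-case paths. The optional MusiQoL
  dimension block emits nine scores whose mean equals the index exactly
  (deviations are centred and shrunk rowwise to respect [0, 100]).

What the generator does **not** emulate: item-level responses, informative
dropout, relapse dynamics, floor effects in severe disability, or any
dependence of the response shift on covariates. Passing recovery tests
therefore shows the pipeline detects weight crossovers under the assumed
correlation and noise structure — not that every real response shift is
detectable.

## Problem sizes used in validation

The statistical acceptance tests run the pipeline at the sizes chosen for
this package's validation study: null calibration with n = 300, K = 30,
50 replicates; recovery and false-positive rates on cohorts of 100 + 400
patients, K = 30 runs per AVI point, 25 trees per forest, 50 replicates
per scenario. K = 30 and the tree count are scaled-down study conditions
relative to the K = 300 / 500-tree analysis defaults; the AVI's K-run
averaging makes the detection behaviour insensitive to this beyond extra
Monte-Carlo noise, which the replicate thresholds (≥ 90% recovery, ≤ 10%
false positives) already absorb.

## Known limitations

* No significance test for AVI curve differences; separation must be
  judged against the reported SDs.
* Permutation importance biases under strongly heterogeneous predictor
  scales/cardinalities are not corrected (no conditional importance).
* Only the reprioritization component of response shift is addressed;
  recalibration and reconceptualization are out of scope.
* The crossing estimator is the linear interpolant of five points; true
  crossing times between visits are resolved only to that precision.
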