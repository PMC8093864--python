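# Methods

This note documents the statistical procedures covnet implements, the
choices made where the methodology is genuinely open, the conditions
the synthetic generators emulate, and the package's known limitations.

## Structural covariance networks

The signal in every analysis is a morphometric index (gray-matter
volume per voxel, cortical thickness per vertex, or an ROI mean)
observed **across subjects** — not a time series.  Covariance
connectivity between two regions is the across-subject correlation of
their signals.

**Nuisance regression.** Covariates of no interest (canonically total
intracranial volume) are removed by ordinary least squares on
`[intercept, covariates]`, applied to *both* the seed and the target
signals before correlating; the correlation's degrees of freedom drop
by the covariate count (`df = n - 2 - c` for seed maps).  Nuisance is
removed first, then the requested correlation is computed — when a
partial ROI-wise correlation is also requested, the remaining ROI
signals are controlled on the residualized data via the precision
matrix (equivalent to the regress-out-then-correlate construction,
which the test suite verifies pair by pair).

**Parametric inference.** p-values use the exact Student-t transform
`t = r sqrt(df / (1 - r^2))`, two-tailed.  Maps are emitted
uncorrected; Benjamini-Hochberg FDR adjustment is available as a
post-hoc flag, not a default.  Zero-variance target features (flat
voxels at a mask edge) get `r = 0, p = 1` with a warning rather than
aborting a whole-brain map; a zero-variance *seed* is an error.

**ROI-wise partial correlation requires more participants than ROIs**
(`n > R + c`); the estimator refuses otherwise with an explicit
message, since the precision matrix is singular at or below that
boundary.

## Causal SCN (cross-sectional Granger causality)

Subjects are sorted ascending by a sequence variable (disease
duration, age); ties keep input order (stable sort).  Along that
pseudo-time axis, for lag `k` (default 1, `k < n/4` enforced):

* restricted model: `Y_n = b0 + beta Y_{n-k} + eps`
* full model: `Y_n = b0 + alpha X_{n-k} + beta' Y_{n-k} + delta`

`eps` and `delta` are **residual variances** (mean squared residual,
same divisor in both models, so the full model can never fit worse and
`F = ln(var_eps / var_delta) >= 0` up to numerical tolerance).  The
residual-based causality statistic is this log variance ratio —
positive exactly when adding the lagged seed improves prediction of
the target — and the coefficient-based statistic is `alpha` itself.
All regressions include an intercept, because morphometric signals are
not mean-centered by construction.

**Order-permutation significance.** The null hypothesis is "the
clinical ordering carries no information", not "the regions do not
covary": each permutation shuffles the subject *order* jointly for
both signals, preserving the cross-sectional x-y pairing.  The
statistic is recomputed per permutation (batched normal-equation
solves keep thousand-permutation nulls in milliseconds) and a normal
distribution fitted to the null gives `z = (obs - mean)/sd` and a
two-tailed p (one-tailed by flag); an empirical-rank p is carried
along for diagnostics.

**Calibration note.** The coefficient statistic has a symmetric
permutation null and its normal-fit p is uniform under the null
(verified at 200 replicates, N=200); the residual-based F is
non-negative and right-skewed, so a *two-tailed normal* tail on it is
conservative/miscalibrated by construction — for calibrated inference
with the residual variant, use the empirical-rank p.  Both variants
agree in direction on coupled pairs.

Exactly collinear pairs (a target identical to the seed) are handled
by pseudo-inverse solves, giving the minimum-norm solution in both the
per-pair and the batched path, so self-maps are symmetric rather than
errors.

## Moderation analysis

`Y = b0 + b1 X + b2 C + b3 (X*C) + b4.. nuisance`, ordinary least
squares, one clinical moderator per fit.  X and C are mean-centered
before forming the product: this leaves `b3` and its t-test unchanged
(verified numerically) but makes `b1` the covariance slope at the mean
clinical value and reduces collinearity.  An intercept is always
included.  ROI-wise output is an asymmetric matrix — entry (i, j) is
the fit with seed i and target j, so the upper triangle holds
seed-to-target effects and the lower triangle target-to-seed.

## Group comparison

Only two groups are supported, by design.

**Subject-regrouping permutation test.** For any connectivity index I
computable on a subject subset, the observed `Delta = I(A) - I(B)` is
referred to the null built by shuffling group labels
(size-preserving), recomputing `Delta'` each time, and fitting a
normal distribution; p is the two-tailed normal tail of
`z = (Delta - mean')/sd'`, with an empirical-rank p alongside.
Nuisance covariates are used as-is under permutation — only labels are
shuffled.  A scalar statistic whose permutation null is constant is an
error; for per-feature statistics (e.g. per-parcel counts), constant
components get NaN z/p with a warning so the informative components
survive.

**Interaction-contrast GLMs.** The two-indicator formulation of a
group-slope model (separate group intercepts plus both group-specific
slopes plus a common slope) is rank-deficient; covnet fits the
mathematically equivalent full-rank single-indicator model
`Y = b0 + bg G + bx X + bgx (G*X) + nuisance` and reports `bgx`, which
is exactly the between-group difference in covariance slope (verified
against two separate per-group regressions).  The moderation contrast
adds the clinical variable and all interactions and reports the
three-way `G*X*C` coefficient.  G indicates the lexicographically
later group label; swapping labels flips the contrast's sign and
nothing else.

**Summary t-test.** Demographic balance is assessed with the
pooled-variance two-sample t from group summary statistics
(`df = n1 + n2 - 2`); Welch's approximation is available by flag.

## Winner-take-all cortex-subcortex labeling

After nuisance residualization, the Pearson correlation between every
(parcel signal, subcortex voxel) pair is computed in one standardized
matrix product; each voxel is labeled by the argmax over *signed* r
with no significance threshold (an optional minimum-r floor relabels
sub-threshold voxels as 0/unassigned, off by default).  Exact ties go
to the lowest parcel index and are logged.  The interface is
generalized to any part-A parcellation against any part-B voxel set,
and is volume-only.  Counts always sum to the subcortex mask size.

The group comparison recomputes the labeling per group (and per
permutation) and tests per-parcel count differences (raw counts by
default, proportions by flag) with the permutation engine.

**A well-posedness caveat.** When labeling is nearly deterministic
(low voxel noise), the count statistic under label shuffling is driven
almost entirely by the group composition of each shuffled subset: the
null becomes a steep, near-bimodal function of composition and the
normal-fit z loses power regardless of how large the true difference
is.  The permutation comparison is informative in the regime where
per-voxel winner probabilities vary smoothly — i.e. sampling noise in
the correlations is comparable to the composition effect.  The
rewiring fixture therefore uses 50 subjects per group, 20 voxels per
block and voxel noise sd 1.5, where detection of a planted
block-rewiring exceeds 90%; at noise sd 0.3 (the recovery fixture) the
same planted effect is near-undetectable by this test, which is a
property of count statistics under full relabeling, not an
implementation artifact.

## Synthetic data

Generators are pure functions of their parameters and `rng_seed`
(bit-identical reruns).  Defaults: 60 subjects in two balanced groups,
a 12x12x12 grid at 2 mm with a 1000-voxel interior mask, Gaussian
latent factors with loading 0.8 against noise sd 0.6, a TIV channel
with loading 0.3, ages uniform on [20, 46].  The causal fixture plants
`y_n = 0.5 y_{n-k} + 0.6 x_{n-k} + noise` along a strictly increasing
synthetic duration; the moderation fixture plants
`y = x (0.2 + 0.8 C)` with C ~ U(0, 1); the WTA fixture plants five
parcel latents driving five voxel blocks.  The demo cohort generator
draws ages and affinely standardizes them so each group's sample mean
and SD match the requested summaries to machine precision — the
pooled t on the generated table equals the summary-statistic t.

What the generators do **not** emulate: spatial smoothness and
autocorrelation of real morphometric maps, registration error,
non-Gaussian tails, site effects, or realistic anatomy.  Passing tests
demonstrate correctness of the estimators and calibration of the
inference under the generative model, not robustness to those
real-data features.

## Numerical choices

* All GLM-family fits solve least squares via `lstsq`/batched normal
  equations and are verified against explicit normal-equation solves
  and statsmodels to 1e-10 on small instances.
* Residual variances in GCA use the same divisor (n_eff) in both
  nested models, guaranteeing `F >= 0`; a zero full-model residual
  yields `F = inf` (perfect prediction) rather than an error.
* Correlations are clipped to [-1, 1] before the t transform; `r = 1`
  maps to `p = 0`.
* Permutations draw from `numpy.random.default_rng(rng_seed)`; a seed
  is required on the CLI whenever permutations are requested.
* Problem sizes in the validation suite (200 replicates x 500
  permutations for calibration, 100 runs for power, 30 runs for WTA
  detection) were chosen so the full suite and the acceptance script
  each complete in well under a minute on a single CPU.

## Limitations

* Pairwise GCA only — no conditional/multivariate causality, no lag
  selection criteria; the pseudo-time construction inherits all the
  caveats of cross-sectional ordering.
* No cluster-level inference (TFCE, cluster extent) and no >2-group
  omnibus tests.
* Surface support is FreeSurfer per-vertex morphometry (curv format
  and 1xV MGH) only; no CIFTI/GIFTI, no DICOM, no preprocessing.
* One clinical moderator per moderation fit.
* The winner-take-all permutation comparison has the power caveat
  described above in near-deterministic labeling regimes.
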