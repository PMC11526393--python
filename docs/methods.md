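# Methods

This note records the statistical model, the algorithmic choices, and the
numerical decisions behind `lvforest`, together with what the built-in
synthetic designs do and do not establish.

## Measurement model

One latent factor η ~ N(μ_η, φ) measured by m ≥ 3 items.  Ordinal item *i*
(categories 1..K_i) follows the conditional-probit graded response model
P(Y_i ≥ k | η) = Φ(λ_i η − κ_{i,k−1}) with strictly increasing thresholds;
equivalently, a normal latent response Y*_i = λ_i η + ε_i, ε_i ~ N(0, 1),
discretized at the κ's.  Numeric items follow Y_i = π_i + λ_i η + ε_i with
free residual variance.  Identification: the reference loading is 1 and the
first threshold of the first ordinal item is 0, leaving μ_η and φ free.  We
parameterize in this conditional (theta) form — residual variances of latent
responses fixed at 1 — so that fitted thresholds and loadings live on the
same scale as the generating values of the synthetic designs; the marginal
statistics being fitted are identical under the delta convention, so this is
a reporting convention, not a different model.

## Two estimators

**Gaussian working ML (tree stage).**  During tree growth all items —
ordinal codes included — are treated as jointly normal with mean π and
covariance φλλ′ + diag(ψ).  This is knowingly misspecified for ordinal data;
its only job is to deliver casewise score functions ψ(y_j, θ̂) cheaply at
every candidate node.  The fit uses sufficient statistics (mean and
covariance), analytic gradients, L-BFGS-B with variance floors at 1e−6;
a fit ending on a floor is flagged as a Heywood case.  Heywood nodes may
still be split (the scores remain usable) but can never become relevant
subgroups.  The information matrix is the outer product of gradients (OPG),
i.e. the sample covariance of the casewise scores — the natural scaling for
an M-estimation fluctuation process and robust to the misspecification.

**Limited-information DWLS (validation stage).**  Stage one estimates
marginal thresholds τ̂ = Φ⁻¹(cumulative proportions), pairwise polychoric
correlations by two-step ML (thresholds fixed; bivariate-normal cell
probabilities via a 64-node Gauss–Legendre quadrature of the
correlation-derivative identity, accurate to ~1e−10), polyserial and Pearson
correlations for numeric items, and the joint asymptotic covariance Γ̂ of all
statistics from casewise influence functions, including the propagation of
threshold-estimation error into the correlation influences (M-estimation
chain rule; the two cross-derivative blocks are obtained by central
differences on the cell-probability tables).  Empty categories are collapsed
into their neighbours and logged.  Stage two minimizes the DWLS discrepancy
— residuals weighted by the inverse square roots of diag(Γ̂) — via
`least_squares`, with starting values from an iterated principal-factor
solution of the polychoric matrix.  Correlations are clipped at ±0.999 with
a warning when association is (near) perfect.

**Fit statistic.**  The raw DWLS quadratic form is a mixture of chi-squares
under a correct model, so the reported T is the mean-and-variance-adjusted
(scaled-shifted) statistic computed from the residual-weight operator
U = W⁻¹ − W⁻¹Δ(Δ′W⁻¹Δ)⁻¹Δ′W⁻¹: T = aT_raw + b with a = √(df/tr[(UΓ̂)²]),
b = df − a·tr(UΓ̂).  Measured under the correct model at n = 500 this is
well calibrated (mean 4.8 for df = 5, 3% rejection at the nominal 5% χ²
critical value), which matters because the same statistic screens terminal
nodes of size ~200–500.  RMSEA uses the population-discrepancy form
√(max(0, (T − df)/(df·n))); the degrees of freedom are the number of fitted
statistics minus the number of free parameters (40 − 35 = 5 for five 7-point
items).

## Instability tests and splitting

The empirical fluctuation process is B(t_j) = Î^{−1/2} n^{−1/2} Σ_{l≤j}
ψ_(l) with observations ordered by a covariate; ties share one evaluation
point (the last row of each tie group).  Statistic families: numeric —
supLM, max of ‖B(t)‖²/(t(1−t)) over t ∈ [0.10, 0.90]; ordinal — the same
functional evaluated only at observed level boundaries; categorical — the LM
statistic Σ_c (n/n_c)‖ΔB_c‖² against χ² with k(C−1) degrees of freedom.
Critical values for the bridge functionals are simulated (default 4,999
replicates; supLM on a 500-point grid) from dedicated RNG streams seeded
deterministically by the statistic's configuration, cached, and shared
across nodes; ordinal boundary fractions are quantized to a 0.01 grid for
cache reuse.  This makes every p-value a pure function of the data — a
prerequisite for caching validation results across trees and for exact
reproducibility — at the cost of reusing one set of null draws per
configuration, whose Monte-Carlo error is far below the decision margins.
Monte-Carlo p-values have a resolution floor of 1/(n_sim + 1); covariates
tied at the floor are ranked by the statistic's standardized exceedance over
its null distribution.  Split points maximize the same score functional over
admissible cuts (both children at least `min_size`); categorical splits
search all binary level partitions up to 10 levels, beyond which levels are
ordered by their mean first score coordinate and scanned like an ordinal
variable.  Measured sizes at n = 500 with k = 15 parameters: supLM 5.3%,
categorical-LM 5.0%, ordinal max-LM 2–4% (slightly conservative).

## The ensemble

Per tree: draw a random subsample *without replacement* (default fraction
0.8 of the data), grow by recursive testing/splitting of `mtry` randomly
drawn covariates per node (Bonferroni level α/mtry), stop on a stable node,
an inadmissible cut, or an ML failure.  Subsampling rather than classic
with-replacement bootstrap is deliberate: duplicated rows clump in the
covariate ordering and give the fluctuation process roughly twice the
variance its OPG scaling assumes, so with a bootstrap every test
over-rejects badly and even homogeneous data get split in every tree
(measured: 10/10 trees split on homogeneous data with a bootstrap, ~5%
split rate with subsampling, matching the nominal level).  The fraction 0.8
reproduces the full-scale study's reported yield of qualifying trees (~4%
per tree) in the heterogeneous benchmark design; 0.632 leaves trees
noticeably shallower and the yield near 1%.

Validation re-applies each terminal rule to the **full sample** (not only
the in-bag rows): re-fit by DWLS, keep the node only if the fit converges
with monotone thresholds, RMSEA ≤ cutoff (default 0.05), and the
M-fluctuation re-assessment against *all* covariates at level α/R finds no
instability.  A split-less root is a valid terminal node — this is what
makes the ensemble collapse to the naive model on homogeneous data.
Because validation is deterministic, regions reappearing in different trees
(keyed by their full-sample row set) are validated once and cached.
Relevant subgroups contribute posterior-mode (EBM) scores to every row their
rule matches; per-row scores are the unweighted mean over matching
subgroups.  Results are bit-reproducible for a fixed master seed: per-tree
generators are spawned from one seed sequence and validation is pure.

EBM scores maximize log N(η; μ̂_η, φ̂) + Σ_i log P(y_i | η) per response
pattern: a 201-point grid over μ̂ ± 8√φ̂ locates the basin and damped Newton
steps polish to ~1e−10; the posterior is log-concave, and the result matches
a dense grid search to 1e−4 (tested).  Patterns are deduplicated, so scoring
costs grow with the number of distinct response patterns, not n.

## Synthetic designs

Three built-in designs emulate heterogeneous measurement:

1. **Ten-subgroup design** (n = 5,000): five 7-point items; per-subgroup
   thresholds, loadings (λ_1 = 1) and factor moments from the fixed tables
   in `lvforest.simulate`; 30 covariates (numeric 1..200, ordinal and
   categorical on 5 points) built so subgroup h is exactly
   {num_h ≤ 50} ∩ {cat_h ∈ {1,3,5}} ∩ {ord_h ≥ 4}, while outside rows that
   satisfy the first two conditions are forced to ord_h ≤ 3 — each subgroup
   is therefore recoverable by a three-condition rule, but ten such rules
   cannot coexist in one tree.
2. **Three-subgroup design** (n = 1,500): eight 5-point items, six
   covariates, two-condition rules; generating parameters are drawn once per
   subgroup from declared samplers (loadings U(0.4, 1.6), thresholds sorted
   N(0, 1.5) draws, Var(η) U(0.5, 1.5), E(η) U(−0.5, 1.5)) spanning the
   ranges of the first design.
3. **Homogeneous control**: one parameter set, covariates independent noise.

Stored ground truth (per-row η and subgroup label) makes score accuracy and
rule recovery directly checkable.  What these designs do *not* emulate:
missing data, local dependence among items, subgroups defined by smooth
covariate effects rather than sharp rules, and covariates correlated with η
within subgroups.  Passing tests therefore demonstrate algorithmic
correctness under clean, rule-defined heterogeneity, not robustness to
messy survey data.

## Problem sizes in the test suite

The validation suite favours many medium-sized checks over one full-scale
run: parameter-recovery checks use n = 50,000–100,000; test-size and
split-recovery properties use 100–1,000 replicates at n = 500–1,000; the
ensemble benchmarks use 50-tree forests for replicated comparisons and a
300-tree reduced ensemble (3% of the 10,000 trees a full-scale analysis
would use) where a single run's covered-subsample accuracy is assessed.
With ~3% of trees yielding a relevant subgroup in the ten-subgroup design,
50-tree ensembles occasionally find none and, when they find one or two,
cover only the purest regions, which biases covered-subsample accuracy
upward; the 300-tree ensemble makes coverage routine while staying around
four minutes on one CPU.

## Known limitations

- Exactly one latent factor; no multidimensional extension.
- The ordinal max-LM test runs slightly conservative at small n, making
  splits on ordinal covariates marginally harder than on numeric ones.
- The polyserial influence functions neglect the sampling error of the
  numeric item's mean and variance (thresholds are propagated); mixed-item
  Γ̂ entries are correspondingly approximate.
- Per-subgroup fits at n ≈ 500 with very skewed items occasionally produce
  large RMSEA excursions driven by a single noisy polychoric correlation
  (about 2% of null realizations exceed 0.06 in the sparsest benchmark
  subgroup); the RMSEA screen inherits the tail behaviour of a maximum over
  many estimated statistics.
- Scores across subgroups are comparable only insofar as the shared
  identification (reference loading, anchored threshold) holds in every
  subgroup; with real DIF in the anchor item itself, averaged scores mix
  scales.
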