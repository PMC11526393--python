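# lvforest

Latent variable scores — factor scores, IRT trait estimates — are only as good
as the measurement model behind them.  When item parameters differ across
subgroups of a sample (differential item functioning, measurement
noninvariance), a single model fitted to everyone produces biased scores, and
the subgroups responsible are rarely known in advance.  `lvforest` implements
a *latent variable forest*: a bagged ensemble of score-based model trees that
searches the covariate space for **relevant subgroups** — regions in which a
one-factor graded response / CFA model both fits well and has
covariate-stable parameters — and estimates each person's latent score by
averaging empirical-Bayes-modal (EBM) scores over all relevant subgroups that
contain them.  It is aimed at psychometricians and survey methodologists
working with ordinal questionnaire scales and a vector of candidate
construct-irrelevant background variables.

## Model and algorithm

The measurement model is a unidimensional graded response model in its
factor-analytic (limited-information) form.  For ordinal item
*i* with categories *k* = 1..K and latent trait η ~ N(μ_η, φ):

    P(Y_i ≥ k | η) = Φ(λ_i η − κ_{i,k−1}),

with loadings λ (reference item fixed at 1) and increasing probit thresholds
κ (first threshold of the first item fixed at 0); numeric items follow
Y_i = π_i + λ_i η + ε_i.  Estimation is two-stage: sample thresholds and
polychoric / polyserial / Pearson correlations first, then diagonally
weighted least squares (DWLS) on the stacked statistics, with a
mean-and-variance-adjusted chi-square and RMSEA.

Each tree in the ensemble is grown on a random subsample.  At every node a
Gaussian working model supplies casewise score functions; generalized
M-fluctuation tests (supLM for numeric covariates, maximal-LM at level
boundaries for ordinal, LM with a chi-square reference for categorical)
probe a random draw of `mtry` covariates for parameter instability at a
Bonferroni-corrected level, and the node splits where the score-based
statistic is maximal.  Terminal nodes are then heavily pruned: the node's
rule is applied to the full sample, the model is re-fitted by DWLS, and the
node is kept only if the fit clears an RMSEA cutoff and an instability
re-assessment against *every* covariate finds nothing.  Survivors are the
relevant subgroups; each contributes EBM scores (posterior modes of η) for
the individuals its rule matches, and scores are averaged per individual
across the ensemble.  Individuals matched by no relevant subgroup stay
unscored — the *nonconvergence rate* reports their share.

## Worked example

The package ships the simulation designs it is validated on.  Ten
heterogeneous subgroups (500 respondents each, five 7-point items, parameters
differing per subgroup) hide behind 30 covariates, such that subgroup *h* is
exactly `{num_h <= 50} & {cat_h in {1,3,5}} & {ord_h >= 4}`:

```python
import numpy as np
from scipy.stats import spearmanr
from lvforest import (ForestConfig, build_covariates, lv_forest,
                      naive_scores, simulate_sim1)

ds = simulate_sim1(np.random.default_rng(1))
y = ds.items.to_numpy()
kinds = {"num": "numeric", "cat": "categorical", "ord": "ordinal"}
cov = build_covariates(ds.covariates,
                       {c: kinds[c.split("_")[0]] for c in ds.covariates})

wls, sc = naive_scores(y, ds.spec)          # one model for everyone
print(f"naive RMSEA {wls.rmsea:.3f}  "
      f"naive accuracy {spearmanr(ds.eta, sc.values).statistic:.3f}")

cfg = ForestConfig(n_trees=100, min_size=200, mtry=2,
                   rmsea_cutoff=0.05, n_sim=1999)
res = lv_forest(y, cov, ds.spec, cfg, seed=42)
m = res.scores.available
print(f"subgroups {len(res.subgroups)}  "
      f"coverage {m.mean():.2f}  "
      f"forest accuracy {spearmanr(ds.eta[m], res.scores.values[m]).statistic:.3f}")
```

Output:

```
naive RMSEA 0.105  naive accuracy 0.685
subgroups 5  coverage 0.31  forest accuracy 0.852
```

The pooled model misfits (RMSEA ≈ 0.105, far above the 0.05 cutoff) and its
scores rank-correlate ≈ 0.69 with the true simulated traits.  The 100-tree
forest recovers five relevant subgroups covering 31% of the sample; on those
rows the averaged subgroup scores reach ≈ 0.85 — close to the ≈ 0.88 achieved
by an oracle that fits each true subgroup separately.  Larger ensembles
increase coverage.

A command-line interface mirrors this:
`lvforest simulate --design sim1 --seed 1 --out data.csv`, then
`lvforest fit --data data.csv --config config.yaml --out results/`, plus
`scores` and `validate` subcommands.

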