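# olfrisk

Does the sense of smell carry early information about diabetes risk? Olfactory
deficits precede several neurological diseases, and metabolic disease has been
proposed as another candidate. `olfrisk` implements, as a reusable and tested
pipeline, the multi-stage statistical framework needed to answer this kind of
question on a cross-sectional cohort: does one feature block (olfactory test
scores) predict a grouping defined by another block (a metabolomics panel, or
a questionnaire-based diabetes risk score)?

Because cohorts of this kind are rarely deposited, the package ships a
synthetic-cohort generator that emulates the statistical structure such a
study reports — and, by default, encodes the *null* configuration in which
olfaction is independent of metabolic risk. The pipeline's job is to say so,
and its permutation controls are there to keep it honest.

## What the pipeline computes

**Cohort structure.** Each subject carries the three Sniffin' Sticks subtests
(odor threshold T, discrimination D, identification I) and their sum, the TDI
score (range 1–48, categorized as functionally anosmic < 16.5, hyposmic
16.5–30.5, normosmic > 30.5); an integer FINDRISK diabetes-risk score mapped
to five categories with 10-year risks of 1 / 4 / 17 / 33 / 50 %; 15
metabolomic variables (10 baseline serum markers + 5 post-glucose-challenge
deltas); and demographic/confounder columns.

**Stages** (each usable on its own):

1. `preprocess` — Kolmogorov–Smirnov-guided transform selection (none / log /
   sqrt / reciprocal), iterated two-sided Grubbs outlier removal (each outlier
   replaced by a missing value), and distance-weighted kNN imputation (k = 3).
2. `modes` — one-dimensional subgroup discovery: Pareto density estimation,
   Gaussian mixture models p(x) = Σᵢ wᵢ N(x | mᵢ, sᵢ) fitted by multi-start
   EM for M = 1..5, model choice by BIC (−2 log L + (3M−1) ln n) with a
   likelihood-ratio and KS backup, and Bayesian decision boundaries at the
   equal-posterior points wᵢ N(x|mᵢ,sᵢ) = wⱼ N(x|mⱼ,sⱼ).
3. `cluster` — correlation-matrix PCA with Kaiser (eigenvalue > 1) retention,
   Ward hierarchical clustering consolidated by centroid-seeded k-means, the
   cluster count chosen by majority vote over ten cluster-number indices, and
   average silhouette width as the quality measure.
4. `assoc` — χ² crosstabs with Pearson residuals (O−E)/√E, a Pearson
   correlation matrix with Bonferroni control, a split-plot rm-ANOVA with
   Greenhouse–Geisser correction, Welch t-tests.
5. `mlharness` — 1000× class-proportional 2/3–1/3 Monte-Carlo cross-validation
   of five classifier families (random forest with 500 trees and ≤ 7 terminal
   nodes, gradient boosting with depth 5 / η 0.25 / 5 parallel trees, an
   entropy decision tree, logistic regression, RBF-SVM), reporting medians and
   2.5–97.5 percentile intervals of balanced accuracy, sensitivity,
   specificity, PPV, NPV, F1 and ROC-AUC — with a negative control that
   refits on freshly permuted training labels every run.
6. `featsel` — Boruta-style shadow-feature testing, cross-validated LASSO and
   LMG relative importance (Shapley decomposition of R²), each re-run on 1000
   Monte-Carlo subsamples; selection frequencies are partitioned by computed
   ABC analysis and the final set is the top-f features by count, f being the
   modal per-run set size.

## Worked example

```python
import numpy as np
from olfrisk import (GeneratorConfig, generate_cohort, fit_gmm,
                     bayes_boundaries, GMMFit)

# the two-mode TDI structure, from its published parameters
fit = GMMFit(means=np.array([24.9, 34.32]), sds=np.array([3.42, 3.2]),
             weights=np.array([0.167, 0.83]) / 0.997,
             log_likelihood=0.0, n=163)
print(round(bayes_boundaries(fit)[0], 2))   # -> 27.85

# a null synthetic cohort: smell says nothing about diabetes risk
table, truth = generate_cohort(GeneratorConfig(seed=7))
print(table.n_subjects, len(table.metabolomic_columns))  # -> 163 15
```

The boundary 27.85 is the TDI value at which the posterior probability of the
low-performance mode equals that of the high-performance mode: subjects below
it are assigned to the reduced-olfaction subgroup.

Running the whole pipeline from a shell:

```bash
olfrisk run-all --seed 1 --runs 200 --out run1
# -> "olfactory features do not improve risk-group prediction"
```

writes per-stage JSON reports, a per-run metric CSV, and a markdown summary
whose classification tables use the `median (2.5–97.5)` convention. On the
default (null) generator, metabolomics-trained classifiers beat chance while
olfactory-trained ones straddle 50 % balanced accuracy, permuted-label
controls sit at 50 %, and olfactory features end up among the rarely-selected
"trivial many" of the ABC analysis — the pipeline's verdict line states
exactly that.

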