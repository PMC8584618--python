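# Methods

This note documents the models, numerical choices and limitations behind
`olfrisk`, in the order the pipeline runs.

## Synthetic cohort generator (`synth`)

The generator emulates a cross-sectional cohort of n = 163 subjects carrying
three blocks: olfactory scores, a diabetes-risk questionnaire score, and a
15-variable metabolomics panel.

**TDI.** Drawn from the two-component Gaussian mixture with means (24.9,
34.32), standard deviations (3.42, 3.2) and weights (0.167, 0.83) — the
published description of the bimodal TDI distribution; the weights sum to
0.997 because they are printed rounded, and the sampler renormalizes. The
draw is decomposed into the three subtests via Dirichlet proportions centred
on (0.25, 0.375, 0.375) with concentration 150, rounded to the instruments'
granularity (0.25 points for threshold, integers for discrimination and
identification), after subtracting an age effect of 0.8 identification
points per age SD (reproducing the well-known negative age–identification
correlation). The final TDI is the sum of the rounded subtests, so the sum
identity holds exactly. No joint T/D/I model is published; this decomposition
is a stand-in whose only claims are the sum identity, plausible marginals and
positive inter-subtest correlation.

**FINDRISK.** Gaussian(11.5, 4) rounded and clipped to [0, 26] — unimodal by
design, since unimodality of the risk score is itself one of the findings the
generator emulates; the parameters roughly reproduce the reported category
counts 19/68/36/33/7. The upper clip is a convention (the instrument's exact
maximum is not published). Age and BMI are generated with correlations of
0.45 and 0.40 to the latent risk score.

**Metabolomics.** Equicorrelated Gaussian blocks (r = 0.3 within the
10-variable baseline block and within the 5-variable delta block) on the
z-scale, then two implanted structures: (i) a latent two-cluster split
(Bernoulli ½) shifting 8 of 15 variables by 2.5 SD (HDL and the
fatty-acid delta in the protective direction) and (ii) a linear risk-score
effect of 0.35 SD per risk SD with the same sign pattern. The shift size was
set so that the stated study condition — PCA/Ward/k-means recovers the two
clusters with label agreement > 0.9 in ≥ 90 % of seeds — actually holds;
1.5 SD does not realize it because the shift direction partly overlaps the
shared within-block correlation factor. z-scores are mapped to reportable
units with per-variable location/scale constants.

**Olfaction–risk association.** Off by default (the null configuration). When
enabled, the latent risk score becomes −e·z(TDI) + √(1−e²)·noise with
e = 0.5, implanting a TDI→risk→metabolome dependence whose recovery is the
framework's power check.

**Injections.** 12 outliers (any metabolomic column; |z| between 8 and 12
relative to pre-injection moments, random sign) and then 6 missing cells
(delta columns only, mimicking skipped post-challenge measurements), matching
the counts reported for the motivating cohort. Latent truth (mode labels,
cluster labels, injected cells) is returned in a sidecar and never written
into the analysis-facing table.

What the generator does **not** emulate: assay measurement-error mechanisms,
the full 38-variable questionnaire block (only two binary confounders),
skewed marginals for lipid variables, or any realistic missingness mechanism
beyond "post-challenge value absent". Tests passing on this generator show
that the pipeline's decision logic behaves as designed under its assumed
structure, not that real metabolomics data satisfy those assumptions.

## Preprocessing (`preprocess`)

Transform selection tests each candidate (none, log, sqrt, reciprocal; log
and reciprocal only for strictly positive data) against a normal with
moment-estimated parameters via the plain Kolmogorov–Smirnov test at
α = 0.05 — no Lilliefors correction, which makes the test anticonservative
but matches its common direct use. The untransformed data win whenever
non-significant; otherwise the largest-p candidate wins; "none" is recorded
if every candidate stays significant.

Grubbs removal is two-sided, one point per iteration,
G = max|xᵢ−x̄|/s against the t-based critical value
((n−1)/√n)·√(t²/(n−2+t²)) with t = t₁₋α/(2n),n−2, iterated until
non-significance or fewer than 3 observed values; removed points become
missing values. α = 0.05 per variable, uncorrected across variables. A
consequence worth knowing: across 15 variables, ~0.5–0.8 false removals per
cohort are expected by construction; the tests therefore check full detection
of injected outliers plus a bounded false-positive budget rather than exact
count equality.

kNN imputation (k = 3) measures row distance as the root-mean-square
difference over standardized, pairwise-complete columns and fills each
missing cell with the inverse-distance-weighted mean of the k nearest rows
observed on that column; exactly-matching rows (zero distance) get uniform
weights. Imputation runs after transform selection and outlier removal and
is idempotent on complete tables.

## One-dimensional mode discovery (`modes`)

The Pareto density estimate uses a uniform kernel whose radius makes the mean
in-ball data fraction ≈ 0.2013, selected among quantiles of the pairwise
distance distribution; the curve is normalized to unit trapezoid integral.
Local maxima are counted with a prominence threshold (5 % of the peak by
default) to suppress the step noise a boxcar kernel produces on finite
samples. Note a fact about the printed TDI mixture itself: its true density
is unimodal (the 0.167-weight component raises a shoulder, not a peak), so
"two PDE peaks" is not a property mixture draws can be expected to show —
component count and density modality are different notions.

Mixtures are fitted by EM with multi-start: one start from a 1-D k-means
(Lloyd) partition of the data plus 7 starts from k-means partitions seeded at
random data points (best final likelihood wins), a variance floor of
(10⁻⁴·data SD)² flagged when triggered, convergence at Δlog L < 10⁻⁸ or 500
iterations, and deterministic behaviour for a fixed seed. Initialization is
part of the estimator's definition here: for weakly separated mixtures at
n ≈ 163 the likelihood surface also carries "broad + narrow" optima (a wide
component underneath a narrow bulk component) that can exceed the
location-separated solution's likelihood; partition-based starts consistently
land on the location-separated basin, which is the scientifically intended
decomposition and what reference mixture fitters return on the same data. The genetic-algorithm optimizer
used in the original workflow is not reimplemented; EM with multi-start
optimizes the same likelihood and the model-selection criteria are what the
conclusions rest on. BIC uses 3M−1 free parameters (simplex-constrained
weights). The likelihood-ratio test against M−1 uses χ²(3) — a pragmatic
convention, since mixture LRTs violate the regularity conditions at the
boundary; it is reported as a descriptive backup to BIC, never as the
decision rule. Goodness of fit is a KS test of the fitted mixture CDF
against the data (replacing visual Q–Q inspection with a computable
quantity). Decision boundaries are Brent roots of the log weighted-density
difference between adjacent means (|Δx| < 10⁻⁶); a pair without a crossing
between its means (extreme sd/weight imbalance) is reported as an absent
boundary rather than fabricated. Published reference BIC values for the
motivating cohort imply that software's own likelihood convention; the
convention here is the one stated above, not claimed numerically identical.

## High-dimensional clustering (`cluster`)

PCA is an eigendecomposition of the correlation matrix; scores are the
standardized data on unit eigenvectors (score variance = eigenvalue,
eigenvalues sum to the variable count), the sign convention makes the
largest-|loading| entry positive, and components with eigenvalue > 1 are
retained (Kaiser rule). Ward clustering uses scipy's Lance–Williams "ward"
criterion on Euclidean distances (the Ward.D2-equivalent); the k-cut
partition seeds a single Lloyd k-means run (tol 10⁻⁶, ≤ 100 iterations),
which cannot increase the within-cluster sum of squares; if a numerical
backend ever returned a worse partition the cut labels would be kept.

The cluster count is a majority vote over ten indices: average silhouette,
Calinski–Harabasz, Davies–Bouldin, Hartigan (H ≤ 10 rule, else largest
drop), Krzanowski–Lai, Dunn, C-index, McClain–Rao, the gap statistic
(10 uniform reference sets over the data's bounding box, one-standard-error
rule) and Ball–Hall (largest successive difference). This is a documented
subset of the 26-index catalogue the original workflow consulted; the
decision rule — modal proposal, ties toward smaller k — is implemented
exactly. Silhouette widths follow the standard (b−a)/max(a,b) with
singletons contributing 0.

## Association statistics (`assoc`)

χ² is plain Pearson without continuity correction (matching the reported
integer dfs), with cell residuals (O−E)/√E and a low-expected-count flag.
The correlation matrix tests all unique off-diagonal pairs, two-sided
t-based p, Bonferroni at α/m. The rm-ANOVA is the classical split-plot
decomposition (one within-subject, one between-subjects factor, complete
balanced within-design required) with Greenhouse–Geisser ε computed from the
double-centred pooled within-group covariance and applied to the within and
interaction dfs; between-factor dfs are integers by construction — the
non-integer between-effect df printed in the motivating report is not
reproducible by a standard mixed ANOVA and is not imitated. Welch t uses
Satterthwaite dfs, with (t, p) = (0, 1) for two equal constant samples.

## Classification harness (`mlharness`)

Splits are class-proportional Monte-Carlo draws: per class,
round(2n_c/3) subjects (clamped to leave at least one on each side) go to
training, the rest to test; every class needs ≥ 3 members. All metric
formulas are implemented directly: sensitivity, specificity, PPV, NPV, F1,
balanced accuracy = (sens+spec)/2, and ROC-AUC by the Mann–Whitney rank
formulation with tie mid-ranks; everything in percent; undefined values
(e.g. PPV with no positive predictions) propagate as NaN, are excluded from
medians/percentiles, and their counts are reported — never silently zeroed.

Classifier defaults follow the study's printed hyperparameters: random
forest with 500 trees, ≤ 7 terminal nodes and mtry = round(√p) (the printed
candidate grid "0.5, 1, 1.5, 2 · nfeatures" is read as multipliers of √p,
the conventional mtry grid; the multiplier is an exposed parameter and no
per-run grid search is performed); boosting with depth 5, learning rate
0.25, 5 parallel trees (50 rounds); an entropy-criterion decision tree
stands in for the proprietary rule inducer (described only as a
non-hierarchical rule-based classifier; no conclusion depends on this
family); logistic regression and an RBF-SVM, both on standardized features.
The backends are standard library estimators behind a fit/predict/score
contract; the harness, permutation logic and all metrics are this package's
own.

The negative control permutes the *training* labels freshly on every run and
leaves test labels untouched: that controls the fitting step, which is what
a permuted-data guard is for. Whether the original analysis permuted once
globally or per run is not documented; per-run permutation is the stricter
choice.

## Feature selection (`featsel`)

The Boruta-style selector appends a column-permuted shadow copy of every
live feature, fits a random-forest regressor, counts a hit when a real
feature's impurity importance beats the maximum shadow importance, and
decides by a two-sided binomial test (success probability ½) with
Bonferroni adjustment across features (the reference implementation's
default): significantly more hits than expected confirms, significantly
fewer rejects and removes the feature (and its shadow) from later forests;
undecided after max_iter (default 100) means not selected, as does a
"tentative" verdict. LASSO selects the nonzero coefficients at the
CV-minimal penalty (minimum-error rule, not one-standard-error — an
interpretation, flagged). LMG importance is the Shapley decomposition of
R²: exact subset enumeration with combinatorial weights for d ≤ 12,
Monte-Carlo over ≥ 200 random orderings beyond; importances sum to the
full-model R².

Each selector is re-run on ⌊2n/3⌋-subject Monte-Carlo subsamples; for LMG a
run's "selected set" is ABC set A of that run's importances (mirroring how
relative-importance output is reduced to a set; an interpretation, flagged).
Computed ABC analysis sorts values descending, builds the cumulative
contribution curve, puts the A|B limit at the point nearest the ideal (0,1)
and the B|C limit at break-even (slope 1, i.e. the last item at or above the
mean), moving A|B to break-even if it would fall later. The final feature
set is the top-f features by count with f the modal per-run set size; count
ties at the cut include all tied features; a flag records any disagreement
between this rule and ABC set-A membership — the two published rules can
conflict and both are reported.

## Orchestration, seeds, problem sizes

`run_pipeline` derives one seed per stage from the master seed via
`SeedSequence.spawn`, logs one structured line per stage, and writes
stage-tagged JSON plus a markdown summary whose tables use the
`median (2.5–97.5)` convention. The verdict is negative when no classifier
family gains ≥ 5 balanced-accuracy points from adding olfactory features and
every olfactory-only interval covers 50 %.

The test suite and the acceptance script size their simulations for a
single-CPU desk run: 20 replicate mixture fits for recovery checks, 10–50
generator seeds for property tests, 80–300 Monte-Carlo CV runs per classifier
family in tests, and the full 1000 runs in the acceptance script's
permuted-forest experiment. These sizes are the package's reporting choices;
all of them are parameters.

## Known limitations

- The generator's Gaussian marginals make the transform-selection stage
  mostly choose "none"; exercising the log/sqrt/reciprocal branches relies on
  dedicated unit fixtures rather than the default cohort.
- The mixture LRT's χ²(3) reference is irregular at the boundary; BIC is the
  operative criterion.
- The 10-index panel is a subset of the 26-index catalogue; on data where the
  absent indices would have swung the majority, votes can differ.
- Boruta false-confirmation behaviour depends on forest size and iteration
  count; the defaults trade power against runtime and are honest but not
  tuned to any external reference.
- With 1 anosmic subject in 163 (as the motivating cohort reports), crosstabs
  involving the anosmia category run with expected counts far below 5; the
  low-expected flag is the package's warning, not a correction.
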