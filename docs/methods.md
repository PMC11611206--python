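# Methods

This note documents the models, conventions and numerical choices behind
`mish`, and what its synthetic benchmarks do and do not establish.

## Copy-number correction (profile)

Stratified metagenome predictions give, per (sample, taxon, enzyme), the
taxon's relative abundance in percent and the taxon's per-genome gene
count. Because 16S-derived abundances over-count taxa with many rRNA
operons, each contribution is divided by the taxon's predicted 16S copy
number before summation:

    x[s, e] = Σ_t  a[s, t] / 100 · g[t, e] / c[t]

The value is used as defined; per-sample renormalization after correction
is deliberately not applied, since the equation already yields a
copy-number-corrected relative abundance and renormalizing would couple
features across enzymes.

* **NSTI filter.** Taxa whose nearest-sequenced-taxon index exceeds
  `nsti_max` are removed before correction. Default 2.0, the conventional
  PICRUSt2 quality cutoff; configurable because survey pipelines differ,
  and parsing tolerates marker files without an NSTI column (filtering is
  then disabled with a warning).
* **Presence** means strictly positive abundance. The prevalence filter
  keeps features present in *more than* `min_fraction` of samples
  (default 1/3, strict inequality — a feature in exactly one third of
  samples is removed). The filter is idempotent.
* **Scaling.** Per-feature min–max to [0, 1]; the (min, max) pairs are
  persisted with every index definition so new cohorts are projected onto
  the training scale and clipped into [0, 1]. Constant features scale to 0
  (not dropped) to keep downstream feature sets aligned; dropping them
  silently would desynchronize saved index definitions.
* EC identifiers are opaque strings; partial ECs (dash placeholders) are
  accepted and flagged.

## Ratings

Indicator values (or residuals from an upstream climate/texture model,
which this package accepts but does not fit) are rated by the
right-continuous ECDF: rating = 100 · (# values ≤ v)/n, matching the
default empirical-distribution-function semantics in R — the maximum rates
100 and the minimum 100/n, never 0. Percentile conventions differ across
software, so this is stated explicitly and tested (n distinct values rate
exactly to 100·(1..n)/n). Ratings are rated over all supplied samples
jointly. Bins are five equidistant intervals, half-open on the right with
100 included in the top bin: [0,20), [20,40), [40,60), [60,80), [80,100].

## Ensemble (stability selection)

Boosted-tree importances are split-dependent; the remedy is repetition.
Defaults follow the survey design: 25 independent 80/20 splits stratified
by climate zone (per-stratum test counts within one sample of the
fraction; strata of size < 2 go to train), 3-fold cross-validation, and
per-split Bayesian optimization of six XGBoost hyperparameters within
these bounds:

| parameter        | range    | role                       |
|------------------|----------|----------------------------|
| eta              | 0.01–0.3 | learning rate              |
| gamma            | 0–5      | split loss threshold       |
| max_depth        | 2–10     | tree depth (integer)       |
| min_child_weight | 1–10     | leaf Hessian floor         |
| lambda           | 0–5      | L2 penalty                 |
| alpha            | 0–5      | L1 penalty                 |

The tuner is a sequential Gaussian-process expected-improvement optimizer
(Matérn-5/2 kernel on the unit cube, random initial block of roughly a
third of the budget, 256-candidate acquisition maximization), deterministic
given the seed; a budget of 1 degenerates to one random configuration.
Boosting rounds are set by early stopping (patience 20 within a 200-round
cap) on the CV folds and the mean best iteration is used for the refit.

Two tuning objectives are exposed. The default treats the 0–100 rating as
continuous (squared error, CV-RMSE selection). An optional
`binarized-auc` mode thresholds the rating at 50 and tunes by AUC —
retained because practice varies on whether such ratings are modelled
continuously or dichotomized; the default is the continuous treatment
since the evaluation metrics (adjusted R², RMSE) are continuous.

Per run, total-gain importances are normalized to sum to 1 so gains are
comparable across runs; the ensemble summary records per enzyme the
presence count (runs with positive gain), the average normalized gain over
those runs, and the full-data Spearman correlation with the rating
(computed on all samples, not per split). Run quality is reported as the
adjusted R² and slope p-value of the observed~predicted OLS on the test
split plus prediction RMSE.

## Index construction and scoring

Stability selection keeps enzymes present in ≥ `presence_min` runs
(default 13 of 25 — a strict majority), ranked by average gain; ties break
by higher presence count, then EC string, so definitions are reproducible.
Enzymes with negative Spearman correlation against the rating are inverted
(x → 1 − x) so that higher always means healthier; an undefined
correlation defaults to +1 with a warning. The score is
100 · Σ w·x′ / Σ w, hence invariant to rescaling all weights, bounded in
[0, 100], and monotone in each feature according to its sign. Missing
enzymes in a scored table impute as scaled 0 *before* inversion (a missing
negatively-signed enzyme therefore contributes its "best" value 1 — the
neutral-absence convention that keeps cross-cohort scoring total).

The enzyme count k is swept over a grid (default 10, 20, …, 100); for each
k the index is built, samples scored, and the index rating regressed on
the indicator rating. The chosen k is the smallest whose adjusted R² is
within a parsimony tolerance (default 0.005) of the grid maximum. AIC
(Gaussian, 3 parameters) is reported alongside for inspection but does not
drive the choice, because "maximum AIC" is not a coherent selection rule;
the R²-plateau-with-parsimony rule is this package's resolution of that
ambiguity. The overall index is the union of each indicator's top k
enzymes; a shared enzyme keeps the maximum gain among its contributors and
the sign of the indicator supplying that maximum (sign conflicts are
resolved by the same rule and logged).

## Evaluation

Score separation across rating bins: Kruskal–Wallis across all bins with
≥ 2 samples, then all pairwise two-sided Wilcoxon rank-sum tests —
exact enumeration when both groups have ≤ 8 samples, otherwise the normal
approximation with continuity correction — adjusted by Benjamini–Hochberg,
and summarized as a compact letter display (insert-and-absorb over the
significance matrix). All three stages were cross-checked against R
(kruskal.test, wilcox.test, p.adjust) to 1e-8 on frozen fixtures. Pathway
composition of selected enzymes comes from a user-supplied EC→pathway TSV
(no database retrieval); a multi-mapping enzyme contributes one
classification per pathway, and proportions are over total classifications
with unmapped enzymes bucketed separately.

## Synthetic data generator

The generator emulates a survey-scale functional profile: per sample a
standard-Gaussian latent per indicator with small climate-zone offsets
(4 zones, offset sd 0.3 by default — enough structure for the stratified
splitter without dominating the signal); signal enzymes as logistic
transforms of (sign·latent + noise); background enzymes as zero-inflated
log-normals with per-enzyme presence probability uniform on (0.05, 0.95),
reproducing the wide prevalence spread of real occurrence data (most
features absent from many samples). Ratings are the ECDF of latent plus
small observation noise (sd 0.05).

The signal noise scale is calibrated from the target Spearman correlation
via the bivariate-normal identity ρ_S = (6/π)·asin(ρ_P/2): invert for the
Pearson target, then sd = sqrt(1/ρ_P² − 1). The logistic squash is
monotone, so Spearman correlations are unaffected while values become
abundance-like and strictly positive; signal enzymes are therefore
ubiquitous, modelling the near-core functions an index would realistically
be built from.

The default conditions are 400 samples × 600 enzymes with 30 signal
enzymes at target |Spearman| 0.5, half negatively signed, across 4 zones —
a deliberately harder-than-typical recovery problem at a size a single CPU
handles in minutes. The benchmark ensemble uses 10 runs with tuning budget
15 at these conditions. What passing shows: the full chain (correction →
scaling → filtering → ensemble → stability selection → signed weighted
mean) recovers planted monotone signals and their directions, and stays at
adjusted R² ≈ 0 under the null. What it does not show: performance under
real-data features the generator omits — phylogenetic correlation among
taxa, compositional coupling between enzymes, nonlinear or interacting
indicator relationships, and measurement error in the indicators
themselves.

A second generator produces taxa-level stratified contribution tables
(Dirichlet relative abundances rescaled to sum to exactly 100, uniform 16S
copy numbers in [1, 8], Poisson gene counts with all-zero genomes bumped to
one gene) together with the expected feature table computed by an explicit
triple loop — the independent oracle for the vectorized profile stage.

## Numerical conventions and degenerate inputs

* All randomness flows from one master seed through `numpy.SeedSequence`
  spawning; XGBoost runs single-threaded (`nthread=1`, `hist`), so full
  pipeline runs are bit-reproducible and the provenance manifest checksums
  agree across repeats.
* Exact-arithmetic claims (correction oracle, score oracle, scaling round
  trip) are tested at 1e-12; statistical cross-checks at 1e-8.
* Constant targets are rejected before tuning; constant predictions score
  adjusted R² 0; a constant feature rates sign +1 with a warning.
* All-identical rating inputs rate 100 with a warning (the ECDF of a
  point mass).
* TSV outputs use `%.12g` floats so manifests are stable across runs.

## Known limitations

* The ensemble assumes one rating column at a time; multivariate targets
  are out of scope.
* The upstream structural-equation residualization that produces
  climate/texture-corrected indicator values is an input, not a
  computation — raw values can be ECDF-rated directly, but they then carry
  whatever climate signal they contain.
* Survey-scale published summary statistics depend on the original
  536-sample national dataset, which is not redistributable; the synthetic
  benchmarks characterize the method, not that dataset.
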