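# Methods

This note documents the models and procedures implemented in `cytoscaffold`,
the defaults they use, and what the synthetic validation does and does not
demonstrate.

## Scope and data model

The pipeline operates on cell × marker expression matrices from mass
cytometry (CyTOF), assumed bead-normalized, debarcoded and gated to live
cells upstream. Values are arcsinh-transformed (`asinh(x / cofactor)`,
cofactor 5 by default — the community convention for metal-isotope
intensities; configurable). Negative raw intensities, which arise after
bead normalization, are kept as-is: truncation would bias the per-sample
medians used later as features.

Markers are split into a **backbone** panel (surface/phenotyping markers
shared between a query dataset and the annotated reference; used for
clustering and annotation) and a **signaling** panel (phospho-proteins and
functional markers; used only for feature engineering). Panel
harmonization is exact string matching after an explicit alias map —
silent fuzzy matches are worse than loud errors. Reference cell types with
fewer than 300 cells are dropped by default; below that, landmark profiles
and per-type training sets are too unstable to trust.

## Reference-guided annotation

Annotation maps query cells onto an annotated reference in four steps:

1. **SOM clustering.** Query cells are clustered on the shared backbone
   with an online self-organizing map, 10×10 grid by default (100
   micro-clusters, comfortably more than the number of phenotypes in
   typical panels). Training: codebook initialized from a random sample of
   cells; per presented cell, the best-matching unit (Euclidean) and its
   grid neighbours move toward the cell under a Gaussian neighbourhood;
   learning rate decays linearly 0.05 → 0.01 and the radius from half the
   larger grid dimension toward zero (floored at 0.3 to avoid a degenerate
   kernel) over 10 passes. All updates are linear in the data, so uniform
   positive rescaling of the inputs rescales the codebook and leaves
   cluster memberships — and hence annotations — unchanged. Training is
   deterministic given the seed.
2. **Query landmarks.** Each occupied SOM node is summarized by the
   arithmetic mean backbone profile of its member cells; empty nodes
   produce no landmark.
3. **Reference landmarks.** One landmark per annotated cell type: the mean
   backbone profile of that type's cells (median available as an option).
   The centroid choice mirrors the construction used for query landmarks.
4. **Matching.** Cosine similarity between every query landmark and every
   reference landmark; each cluster takes the label of its most similar
   reference landmark, ties broken toward the first label in sorted order
   (determinism over elegance), and member cells inherit the cluster
   label. An optional similarity threshold relabels low-confidence
   clusters `unassigned`; the default applies no threshold, since useful
   thresholds are dataset-dependent.

By default each sample is clustered independently (matching per-patient
annotation practice); pooled clustering is available. KNN (k ∈ {3, 10},
majority vote, vote ties broken by the nearest neighbour's label) and LDA
(argmax posterior, no rejection) are provided as supervised per-cell
baselines, and a stratified hold-out self-consistency protocol scores any
method one-vs-all per cell type.

## DREMI

For a directed pair X → Y, the conditional-density resampled mutual
information asks how the *distribution* of Y shifts across states of X,
deliberately ignoring where the joint density concentrates:

- Gaussian-kernel density estimate of the joint on a 256 × 256 grid
  spanning the observed range of each axis (expanded by one bandwidth),
  implemented as a binned KDE (linear histogram + separable Gaussian
  filter) for speed;
- aggregation to 8 × 8 coarse states; each X-column with at least 1% of
  the uniform column mass is renormalized into p(y|x), lighter columns are
  excluded;
- mutual information of the conditionals with **equal weight on every
  retained X-state**: score = Σ_x w(x) Σ_y p(y|x) log₂(p(y|x)/q(y)), with
  w uniform and q(y) = Σ_x w(x) p(y|x). The equal weighting implements
  the density "resampling" as an exact reweighting — deterministic, and
  identical in expectation to stochastic resampling.

Scores are in bits, bounded by log₂(8) = 3, and directional: X → Y and
Y → X generally differ. Because the grid adapts to the data range, any
strictly increasing affine transform of either marker leaves the score
essentially unchanged.

**Bandwidth.** The default kernel width is one fine-grid cell per axis
("grid" rule). The kernel's job here is to regularize the histogram at the
resolution of the fine grid, *not* to produce a smooth marginal: a
marginal-oriented bandwidth (Silverman's rule, ~10 fine cells at n = 10⁴)
blurs density across coarse states and caps a noiseless Y = X relation
near 2.0 of the 3 attainable bits, destroying exactly the conditional
sharpness the score exists to measure (with the grid rule the same data
score ≈ 2.78). Silverman and fixed numeric bandwidths remain selectable,
and every result records the estimator settings used. A minimum of 200
cells is required per estimate; with fewer cells the 64-state conditional
table is too sparse, and samples below the minimum are masked rather than
imputed. At a few hundred cells the plug-in estimate retains a positive
bias (sparse columns look deterministic); the bias is shared across
samples estimated with the same settings, so *differences* between
samples — what the downstream models consume — remain informative.

## Feature engineering

Per cell type and sample: **median features** (one per signaling marker)
or **DREMI features** (all ordered pairs X → Y, X ≠ Y: p(p−1) features,
210 for a 15-marker panel). Pair order is fixed lexicographically in the
configured panel order so feature columns are stable across runs and
cohorts. Samples failing the min-cell rule are masked and dropped for that
cell type's model — never imputed, which would fabricate
mutual-information values.

## Class rebalancing (SMOTE)

Survival cohorts are imbalanced (e.g. 28 short-term vs 15 long-term
survivors). SMOTE generates synthetic minority samples as uniform points
on segments between a minority sample and one of its k = 5 nearest
minority neighbours, so synthetic points stay inside the minority convex
hull. The interface takes the *target ratio* (1:1, 1:2, 1:3) and derives
the oversampling and majority-draw amounts: minority is raised to
max(original, ⌈a/b · majority⌉) for ratio a:b with all original minority
points retained, and the majority is drawn to make the ratio exact —
without replacement when it has enough members (plain undersampling), with
replacement otherwise (the requested balance is more majority-heavy than
the data; e.g. 1:2 or 1:3 from 15/28 needs 30 or 45 majority draws from
28 available). Rebalancing is applied to the training partition only;
synthetic samples never reach validation or test sets.

## Survival classification protocol

Binary STS (< 60 months from diagnosis) vs LTS (≥ 60), one model per cell
type. Per repeat: a stratified random split takes 20% (or 50%) of samples
for testing; 40% of the remainder forms the validation set; optional SMOTE
is applied to the training partition; the hyper-parameter — XGBoost
maximum tree depth over [2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 30, 40, 50,
60], or the penalty weight for L1 ("lasso") / L2 ("ridge") logistic
regression over a log-spaced grid — is chosen to maximize validation F1,
ties toward the simplest model (smallest depth, strongest penalty); the
chosen configuration is refit on train + validation and scored on the test
set (SEN, SPE, F1 at probability threshold 0.5, plus rank-based AUC).
XGBoost's non-tuned settings are pinned: 100 boosting rounds, learning
rate 0.3, binary logistic objective, all configurable. The split is
seeded per (protocol seed, repeat index), so any repeat is reproducible in
isolation. Note on the regression baselines: some descriptions of the
underlying glmnet tool invert the meaning of its `alpha` parameter; here
the standard convention is used (lasso = pure L1, ridge = pure L2).

Over n repeats (100 by default; 1000 recommended for importance studies)
the per-repeat metrics are averaged arithmetically, and per-feature
XGBoost gain is aggregated into a selection count (runs using the feature
in ≥ 1 split) and a mean gain over those runs, sorted by (count, gain).
A helper splits samples into low/high groups at the cohort-median score
(ties low) for downstream Kaplan–Meier / Cox analyses, which are
deliberately left to standard survival libraries.

## Synthetic data

The generator emulates the structure the pipeline assumes, with defaults
mirroring the case-study shape: 7 cell types, a 15-marker backbone, 15
signaling markers, 28 STS + 15 LTS samples.

- Cell types are isotropic Gaussians (σ = 0.2) in arcsinh space around
  high/low signature profiles redrawn until every pair has cosine
  similarity ≤ 0.7 — "well separated" by design.
- Per-sample cell-type abundances follow a symmetric Dirichlet
  (concentration 10), giving realistic composition variability while
  keeping most samples above the 200-cell DREMI minimum at the default
  3,000 cells per sample (a desk-scale stand-in for the ~150,000 cells
  per patient of a real cohort).
- Planted dependencies overwrite Y = β_group · X + ε (σ_ε = 0.25) for a
  chosen cell type and directed signaling pair, with separate slopes per
  outcome group — the known discriminative signal.
- Survival months are drawn uniform on [2, 59] (STS) or [60, 140] (LTS),
  consistent with the 60-month rule.

What passing on this generator shows: the pipeline recovers planted
structure (cluster labels, directed dependencies, group differences) when
its assumptions hold. What it does not show: robustness to heavy-tailed
marginals, batch effects, spillover, doublets, or phenotypes that violate
the separation cap — real-data performance must be established on real
cohorts.

## Numerical and degenerate-input choices

- BMU assignment and argmax-similarity ties go to the lowest index /
  first sorted label; k-NN vote ties to the nearest neighbour's label.
- Metrics with zero denominators are reported as flagged-undefined, never
  silently zero — averaging zeros in would depress macro scores for rare
  classes. Macro averages are unweighted over classes where defined.
- Zero-variance inputs are rejected where a direction or density is
  undefined (cosine of a zero vector, DREMI on a constant marker,
  median-stratification of constant scores).
- DREMI scores are clipped at 0 from below for numerical noise; the
  log₂(8) upper bound is exact by construction.
- Stratified splits retry (fresh randomness, bounded attempts) when
  rounding leaves a class out of a partition, then fail loudly.

## Validation problem sizes

The test-suite and acceptance-script runs use desk-scale sizes chosen to
exercise every code path at stable statistics: references of 7 × 1,000
cells, cohorts of 43 samples × 700–3,000 cells, 6-marker signaling panels
(30 directed features) for end-to-end recovery runs, 25–100 protocol
repeats with a reduced depth grid [2, 4, 6] and 30 boosting rounds, and
n = 10,000 draws for DREMI calibration. Null calibration of the repeated
protocol is averaged over independently generated cohorts: on any *single*
small cohort, chance correlations between noise features and labels induce
negative train/test dependence across repeated splits, so a one-cohort
mean AUC can sit well off 0.5 without anything being wrong.

## Known limitations

- Reference landmark construction (per-type centroids) and SOM
  hyper-parameters are reasonable fixed choices, not fitted to any
  external implementation; annotation quality on real data depends on
  panel compatibility and reference quality.
- The DREMI estimator's hyper-parameters (grid sizes, bandwidth rule,
  column-exclusion mass) are recorded per result; scores are comparable
  only across identical settings.
- The FCS reader covers list-mode FCS 3.0/3.1 with float, double and
  byte-aligned integer data — the formats cytometers emit in practice —
  and does not parse analysis segments or multi-dataset files.
- No GUI or graph visualization of the landmark map is provided.
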