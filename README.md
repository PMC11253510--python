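# cytoscaffold

Reference-guided cell-type annotation and signaling-dynamics features for
mass cytometry (CyTOF), with cell-type-specific machine-learning models of
patient survival.

## The problem

CyTOF quantifies 30+ proteins per single cell across millions of cells per
patient. Two analysis steps dominate the effort: (1) assigning cells to
biological cell types — manual gating does not scale, and unsupervised
clustering needs subjective post-hoc labelling; and (2) turning per-cell
signaling measurements into patient-level predictors — single-value
summaries such as the median discard most of the single-cell information.

`cytoscaffold` addresses both for researchers analysing clinical CyTOF
cohorts:

- **Annotation** maps query cells onto an annotated reference dataset:
  cells are clustered with a self-organizing map (10×10 grid) on the
  backbone markers shared between the panels, each cluster is summarized
  by its centroid ("landmark"), and every cluster takes the cell type of
  the reference landmark with the highest cosine similarity. KNN and LDA
  per-cell classifiers are included as baselines, with one-vs-all
  ACC/SEN/SPE/F1 evaluation.
- **Feature engineering** builds per-cell-type, per-sample feature
  matrices: median signaling expression, or the **DREMI** score of every
  directed marker pair. DREMI (conditional-density resampled mutual
  information) measures how the distribution of protein Y shifts across
  the states of protein X,

      DREMI(X→Y) = Σₓ w(x) Σ_y p(y|x) log₂ ( p(y|x) / q(y) ),

  with uniform weights w over populated X-states and q(y) = Σₓ w(x) p(y|x);
  it is directional (X→Y ≠ Y→X) and captures responses the joint density
  hides. A 15-marker panel yields 15·14 = 210 directed features.
- **Survival modelling** casts short- vs long-term survival (60-month
  cutoff) as binary classification per cell type: repeated stratified
  hold-out (100×), SMOTE rebalancing of the training partition to exact
  target ratios, XGBoost depth tuning on validation F1 (lasso/ridge
  logistic regression as baselines), and feature-importance aggregation
  (mean gain × selection frequency) across repeats.
- **Synthetic data** generates CyTOF-like references and cohorts with
  known ground truth — separated cell-type clusters in arcsinh space,
  Dirichlet abundance variation, planted directed dependencies whose
  strength differs between outcome groups — so the whole pipeline is
  testable without any external download.

## Worked example

Generate a 43-sample cohort (28 STS / 15 LTS) in which a single directed
dependency — pErk→pP38 in monocytes, slope 2 in short-term survivors,
absent in long-term survivors — carries the outcome signal, then recover
it end to end:

```python
from cytoscaffold import (
    SyntheticSpec, PlantedPair, generate_cohort, generate_reference,
    annotate, dremi_pair_features, repeated_protocol, ProtocolConfig,
    aggregate_importance,
)

spec = SyntheticSpec(
    signaling_dim=6, cells_per_sample=3000,
    planted_pairs=(PlantedPair("Monocytes", "pErk", "pP38",
                               beta_sts=2.0, beta_lts=0.0),),
    seed=11,
)
reference = generate_reference(spec)
cohort = generate_cohort(spec)

pooled = cohort.pooled_matrix()
res = annotate(pooled, reference, backbone=list(spec.backbone_names),
               seed=11, per_sample=False)
print(f"annotation accuracy vs ground truth: "
      f"{(res.cell_labels == pooled.cell_labels).mean():.4f}")

fm = dremi_pair_features(pooled, "Monocytes",
                         list(spec.signaling_names)).drop_masked()
labels = cohort.survival.labels_for(fm.sample_ids)
cfg = ProtocolConfig(n_repeats=25, depth_grid=(2, 4, 6),
                     n_boost_rounds=30, seed=11)
result = repeated_protocol(fm, labels, cfg)
m = result.mean_metrics()
print(f"mean test metrics over 25 repeats: SEN={m['SEN']:.3f} "
      f"SPE={m['SPE']:.3f} F1={m['F1']:.3f} AUC={m['AUC']:.3f}")
top = aggregate_importance(result.importance_records).table.iloc[0]
print(f"top feature: {top['feature']} (selected in "
      f"{top['selection_count']}/25 runs, mean gain {top['mean_gain']:.2f})")
```

Output:

```
annotation accuracy vs ground truth: 1.0000
mean test metrics over 25 repeats: SEN=0.893 SPE=1.000 F1=0.938 AUC=0.947
top feature: pErk->pP38 (selected in 25/25 runs, mean gain 7.41)
```

Every cell recovers its generating type; the survival models separate the
groups (AUC 0.95), and the planted pair is the single most selected
feature in all 25 repeats — the pipeline finds exactly the signal that was
planted, in the right cell type and the right direction.

## Command line

The same stages are available as a CLI:

```bash
cytoscaffold simulate --spec spec.yaml --seed 7 --out data/
cytoscaffold annotate --query sample.fcs --reference ref.csv \
    --grid 10x10 --seed 7 --out labels.csv
cytoscaffold dremi --input cells.csv --x pP38 --y pSTAT3 --out score.json
cytoscaffold features --cells cells.csv --mode dremi \
    --cell-type Monocytes --signaling pErk,pP38,pS6 --out feats.csv
cytoscaffold predict --features feats.csv --labels clinical.csv \
    --smote 1:1 --repeats 100 --seed 7 --out report.json
cytoscaffold run --config pipeline.yaml   # full chained pipeline
```

Inputs: FCS 3.0/3.1 or delimited text (header row = marker names; reserved
columns `__label__` / `__sample__` carry cell labels and sample ids);
sample-level clinical tables as CSV/TSV. Exit codes: 0 success, 2 config
error, 3 data error, 4 internal error.

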