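"""Reference-guided cell-type annotation via landmark matching.

The approach maps query cells onto an annotated reference in four steps:

1. cluster the query cells with a self-organizing map on the shared
   ("backbone") phenotyping markers;
2. summarize each occupied SOM node by its centroid — a query *landmark*;
3. compute cosine similarity between every query landmark and every
   reference landmark (one per annotated cell type);
4. label each cluster with the cell type of its most similar reference
   landmark, and let every member cell inherit that label.

KNN and LDA per-cell classifiers are provided as supervised baselines, and
a self-consistency protocol scores any of the methods on a stratified
hold-out split of a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestNeighbors

from .data_model import ExpressionMatrix, PanelConfig, ReferenceDataset
from .errors import ConfigError, DataError
from .evaluation import EvalReport, evaluate_multiclass
from .som import SOMModel, assign_to_nodes, train_som

__all__ = [
    "LandmarkSet",
    "AnnotationResult",
    "compute_query_landmarks",
    "compute_reference_landmarks",
    "cosine_similarity",
    "cosine_similarity_matrix",
    "annotate",
    "baseline_knn",
    "baseline_lda",
    "self_consistency_protocol",
]

UNASSIGNED = "unassigned"


@dataclass
class LandmarkSet:
    """Labeled profile vectors over backbone markers."""

    profiles: np.ndarray  # n_landmarks x backbone_dim
    labels: list[str]
    member_counts: np.ndarray
    backbone: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=np.float64)
        self.member_counts = np.asarray(self.member_counts, dtype=int)
        if len(self.labels) != self.profiles.shape[0]:
            raise DataError("one label per landmark required")
        if (self.member_counts == 0).any():
            raise DataError("landmarks with zero members must be dropped")


@dataclass
class AnnotationResult:
    """Output of :func:`annotate`.

    ``cell_labels`` is positional over the query cells. ``similarities`` has
    one row per query cluster and one column per reference landmark.
    """

    cell_labels: np.ndarray
    cluster_ids: np.ndarray
    cluster_labels: list[str]
    cluster_best_similarity: np.ndarray
    similarities: np.ndarray
    reference_labels: list[str]
    threshold: float | None = None


def compute_query_landmarks(
    X: np.ndarray, cluster_ids: np.ndarray, backbone: Sequence[str] | None = None
) -> tuple[LandmarkSet, np.ndarray]:
    """Per-cluster centroid profiles; empty clusters produce no landmark.

    Returns the landmark set and the sorted array of occupied cluster ids
    (parallel to the landmark rows).
    """
    X = np.asarray(X, dtype=np.float64)
    cluster_ids = np.asarray(cluster_ids)
    if X.shape[0] != cluster_ids.shape[0]:
        raise DataError("one cluster id per cell required")
    occupied, inverse, counts = np.unique(
        cluster_ids, return_inverse=True, return_counts=True
    )
    profiles = np.zeros((occupied.size, X.shape[1]))
    np.add.at(profiles, inverse, X)
    profiles /= counts[:, None]
    landmarks = LandmarkSet(
        profiles=profiles,
        labels=[str(c) for c in occupied],
        member_counts=counts,
        backbone=list(backbone or []),
    )
    return landmarks, occupied


def compute_reference_landmarks(
    ref: ReferenceDataset,
    backbone: Sequence[str],
    statistic: str = "mean",
) -> LandmarkSet:
    """One landmark per annotated cell type: its centroid backbone profile.

    Cell types are ordered canonically (sorted) so that downstream argmax
    tie-breaking is deterministic. ``statistic`` may be ``mean`` (default)
    or ``median``.
    """
    if statistic not in {"mean", "median"}:
        raise ConfigError("statistic must be 'mean' or 'median'")
    sub = ref.matrix.subset_markers(list(backbone))
    labels = ref.matrix.cell_labels.astype(str)
    types = sorted(np.unique(labels))
    profiles, counts = [], []
    reducer = np.mean if statistic == "mean" else np.median
    for t in types:
        mask = labels == t
        profiles.append(reducer(sub.values[mask], axis=0))
        counts.append(int(mask.sum()))
    return LandmarkSet(
        profiles=np.array(profiles),
        labels=types,
        member_counts=np.array(counts),
        backbone=list(backbone),
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); undefined (error) for zero vectors."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise DataError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DataError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row cosine similarities between two profile matrices."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if (na == 0).any() or (nb == 0).any():
        raise DataError("cosine similarity undefined for zero-profile landmarks")
    return (A @ B.T) / np.outer(na, nb)


def annotate(
    query: ExpressionMatrix,
    ref: ReferenceDataset,
    cfg: PanelConfig | None = None,
    backbone: Sequence[str] | None = None,
    grid: tuple[int, int] = (10, 10),
    threshold: float | None = None,
    per_sample: bool = True,
    landmark_statistic: str = "mean",
    seed: int = 0,
    som_kwargs: dict | None = None,
) -> AnnotationResult:
    """Annotate query cells against an annotated reference.

    When ``backbone`` is omitted it is derived as the shared panel between
    query and reference (restricted to ``cfg.backbone_markers`` if given).
    With ``per_sample=True`` (default) and sample ids present, each sample
    is clustered independently — matching per-patient annotation — and the
    per-sample cluster ids are offset so they remain globally unique.
    A cluster whose best similarity falls below ``threshold`` is labeled
    ``"unassigned"``.
    """
    from .data_model import harmonize_panels

    if backbone is None:
        backbone = harmonize_panels(query, ref.matrix, cfg)
    backbone = list(backbone)
    ref_landmarks = compute_reference_landmarks(
        ref, backbone, statistic=landmark_statistic
    )
    q = query.subset_markers(backbone)

    n = q.n_cells
    cluster_ids = np.full(n, -1, dtype=int)
    if per_sample and query.sample_ids is not None:
        groups = [
            np.flatnonzero(query.sample_ids == s)
            for s in pd_unique(query.sample_ids)
        ]
    else:
        groups = [np.arange(n)]

    offset = 0
    som_kwargs = dict(som_kwargs or {})
    for g_i, idx in enumerate(groups):
        som = train_som(
            q.values[idx], rows=grid[0], cols=grid[1], seed=seed + g_i, **som_kwargs
        )
        cluster_ids[idx] = assign_to_nodes(som, q.values[idx]) + offset
        offset += som.n_nodes

    q_landmarks, occupied = compute_query_landmarks(q.values, cluster_ids, backbone)
    sims = cosine_similarity_matrix(q_landmarks.profiles, ref_landmarks.profiles)
    best_idx = np.argmax(sims, axis=1)  # ties -> first label in canonical order
    best_sim = sims[np.arange(sims.shape[0]), best_idx]
    cluster_labels = [ref_landmarks.labels[j] for j in best_idx]
    if threshold is not None:
        cluster_labels = [
            lab if s >= threshold else UNASSIGNED
            for lab, s in zip(cluster_labels, best_sim)
        ]

    label_of = dict(zip(occupied.tolist(), cluster_labels))
    cell_labels = np.array([label_of[c] for c in cluster_ids], dtype=object)
    return AnnotationResult(
        cell_labels=cell_labels,
        cluster_ids=cluster_ids,
        cluster_labels=cluster_labels,
        cluster_best_similarity=best_sim,
        similarities=sims,
        reference_labels=list(ref_landmarks.labels),
        threshold=threshold,
    )


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance (cell order is meaningful)."""
    import pandas as pd

    return pd.unique(values)


def baseline_knn(
    train_X: np.ndarray,
    train_labels: Sequence,
    test_X: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """Euclidean k-nearest-neighbour majority vote.

    Vote ties are broken by the label of the single nearest neighbour.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_labels = np.asarray(train_labels, dtype=object)
    test_X = np.asarray(test_X, dtype=np.float64)
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > train_X.shape[0]:
        raise DataError(f"k={k} exceeds training size {train_X.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(train_X)
    _, idx = nn.kneighbors(test_X)  # columns ordered by increasing distance
    out = np.empty(test_X.shape[0], dtype=object)
    for i, row in enumerate(idx):
        labs = train_labels[row]
        uniq, counts = np.unique(labs.astype(str), return_counts=True)
        winners = set(uniq[counts == counts.max()])
        if len(winners) == 1:
            out[i] = next(iter(winners))
        else:
            out[i] = next(str(l) for l in labs if str(l) in winners)
    return out


def baseline_lda(
    train_X: np.ndarray,
    train_labels: Sequence,
    test_X: np.ndarray,
) -> np.ndarray:
    """Linear discriminant classification; argmax posterior, no rejection."""
    train_labels = np.asarray(train_labels, dtype=object).astype(str)
    classes, counts = np.unique(train_labels, return_counts=True)
    if classes.size < 2:
        raise DataError("LDA requires at least two classes")
    if (counts < 2).any():
        raise DataError("LDA requires at least two cells per class")
    lda = LinearDiscriminantAnalysis()
    try:
        lda.fit(np.asarray(train_X, dtype=np.float64), train_labels)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DataError(
            "singular within-class covariance; reduce markers or add shrinkage "
            "by preprocessing features"
        ) from exc
    return lda.predict(np.asarray(test_X, dtype=np.float64)).astype(object)


def self_consistency_protocol(
    ref: ReferenceDataset,
    backbone: Sequence[str] | None = None,
    train_frac: float = 0.8,
    methods: Sequence[str] = ("scaffold",),
    grid: tuple[int, int] = (10, 10),
    seed: int = 0,
) -> dict[str, EvalReport]:
    """Hold-out evaluation of annotation methods on one reference dataset.

    Cells are split per cell type (stratified) into a training part — which
    plays the reference role for scaffold, or the supervised training set
    for KNN/LDA — and a testing part scored one-vs-all per cell type.
    ``methods`` entries: ``scaffold``, ``knn3``, ``knn10``, ``lda``.
    """
    if not 0 < train_frac < 1:
        raise ConfigError("train_frac must be in (0, 1)")
    labels = ref.matrix.cell_labels.astype(str)
    types = np.unique(labels)
    if types.size < 2:
        raise DataError("self-consistency needs at least two cell types")
    if backbone is None:
        backbone = list(ref.matrix.marker_names)
    backbone = list(backbone)

    rng = np.random.default_rng(seed)
    train_mask = np.zeros(labels.size, dtype=bool)
    for t in types:
        idx = np.flatnonzero(labels == t)
        rng.shuffle(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_mask[idx[:n_train]] = True
    if not all((labels[train_mask] == t).any() for t in types):
        raise DataError("a cell type is absent from the training split")

    train = ref.matrix.subset_cells(train_mask)
    test = ref.matrix.subset_cells(~train_mask)
    train_X = train.subset_markers(backbone).values
    test_X = test.subset_markers(backbone).values
    truth = test.cell_labels.astype(str)

    reports: dict[str, EvalReport] = {}
    for method in methods:
        if method == "scaffold":
            train_ref = ReferenceDataset(matrix=train)
            res = annotate(
                test, train_ref, backbone=backbone, grid=grid,
                per_sample=False, seed=seed,
            )
            pred = res.cell_labels
        elif method in {"knn3", "knn10"}:
            k = int(method[3:])
            pred = baseline_knn(train_X, train.cell_labels, test_X, k=k)
        elif method == "lda":
            pred = baseline_lda(train_X, train.cell_labels, test_X)
        else:
            raise ConfigError(f"unknown annotation method {method!r}")
        reports[method] = evaluate_multiclass(truth, pred, classes=sorted(types))
    return reports
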