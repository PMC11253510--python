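"""Cell-type-specific prediction of short- vs long-term survival.

The task is binary classification of patient samples into short-term
(STS, survival < 60 months from diagnosis) versus long-term (LTS)
survivors, from per-cell-type feature matrices (median or DREMI features).
The protocol mirrors repeated hold-out evaluation:

- a stratified random split into test (20% or 50%) and a training/
  validation pool, of which 40% is the validation set;
- optional SMOTE rebalancing of the *training partition only* — synthetic
  samples never reach validation or test;
- hyper-parameter tuning (XGBoost tree depth, or the penalty weight for
  L1/L2 logistic regression) maximizing validation F1, ties resolved
  toward the simplest model;
- the chosen configuration refit on train+validation and scored on the
  held-out test set;
- the whole cycle repeated ``n_repeats`` times with fresh random splits,
  reporting per-repeat SEN/SPE/F1/AUC and their means, plus per-feature
  XGBoost gain and selection frequency aggregated over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression

from .errors import ConfigError, DataError
from .evaluation import auc_score, metrics_from_counts, one_vs_all_counts
from .features import FeatureMatrix
from .imbalance import SmoteConfig, smote_resample

__all__ = [
    "ProtocolConfig",
    "ImportanceSummary",
    "RepeatedRunResult",
    "split_holdout",
    "tune_and_train",
    "repeated_protocol",
    "aggregate_importance",
    "stratify_by_median",
]

DEFAULT_DEPTH_GRID = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 30, 40, 50, 60)
DEFAULT_C_GRID = tuple(10.0**e for e in range(-3, 4))
POSITIVE_LABEL = "STS"


@dataclass(frozen=True)
class ProtocolConfig:
    """Settings of the repeated hold-out protocol."""

    test_frac: float = 0.2
    val_frac_of_train: float = 0.4
    n_repeats: int = 100
    depth_grid: tuple[int, ...] = DEFAULT_DEPTH_GRID
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_boost_rounds: int = 100
    learning_rate: float = 0.3
    smote: SmoteConfig | None = None
    pos_label: str = POSITIVE_LABEL
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_frac < 1 or not 0 < self.val_frac_of_train < 1:
            raise ConfigError("fractions must lie in (0, 1)")
        if not self.depth_grid or not self.c_grid:
            raise ConfigError("hyper-parameter grids must be non-empty")
        if self.n_repeats < 1 or self.n_boost_rounds < 1:
            raise ConfigError("n_repeats and n_boost_rounds must be positive")


@dataclass
class ImportanceSummary:
    """Per-feature mean gain and selection frequency over repeated runs."""

    table: pd.DataFrame  # columns: feature, selection_count, mean_gain
    n_repeats: int

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


@dataclass
class FittedModel:
    algorithm: str
    model: object
    chosen_param: float
    feature_names: list[str]

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        if self.algorithm == "xgboost":
            proba = self.model.predict_proba(np.asarray(X, dtype=np.float64))
        else:
            proba = self.model.predict_proba(np.asarray(X, dtype=np.float64))
        classes = list(self.model.classes_)
        return proba[:, classes.index(1)]

    def gain_importance(self) -> dict[str, float]:
        """Average split gain per feature actually used (XGBoost only)."""
        if self.algorithm != "xgboost":
            raise ConfigError("gain importance is defined for xgboost models")
        booster = self.model.get_booster()
        raw = booster.get_score(importance_type="gain")
        return {self.feature_names[int(k[1:])]: float(v) for k, v in raw.items()}


@dataclass
class RepeatedRunResult:
    """Per-repeat test metrics and importance records for one cell type."""

    cell_type: str
    algorithm: str
    per_repeat: pd.DataFrame  # columns: repeat, SEN, SPE, F1, AUC, chosen_param
    importance_records: list[dict[str, float]] = field(default_factory=list)

    @property
    def n_classifiers(self) -> int:
        return len(self.per_repeat)

    def mean_metrics(self) -> dict[str, float]:
        return {
            m: float(self.per_repeat[m].mean(skipna=True))
            for m in ("SEN", "SPE", "F1", "AUC")
        }


def _derive_seed(seed: int, repeat_index: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(repeat_index, salt))
    )


def split_holdout(
    labels: Sequence,
    cfg: ProtocolConfig,
    repeat_index: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified (train, validation, test) index arrays for one repeat.

    Test takes ``test_frac`` of each class (rounded, at least one sample);
    validation takes ``val_frac_of_train`` of the remainder. Partitions are
    disjoint and exhaustive. If rounding leaves a class absent from any
    partition the draw is retried (fresh randomness) up to 100 times.
    """
    y = np.asarray(labels, dtype=object).astype(str)
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("both classes must be present to split")
    for attempt in range(100):
        rng = _derive_seed(cfg.seed, repeat_index, salt=attempt)
        train, val, test = [], [], []
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            n_test = int(round(cfg.test_frac * idx.size))
            n_test = min(max(n_test, 1), idx.size - 2)
            rest = idx[n_test:]
            n_val = int(round(cfg.val_frac_of_train * rest.size))
            n_val = min(max(n_val, 1), rest.size - 1)
            test.append(idx[:n_test])
            val.append(rest[:n_val])
            train.append(rest[n_val:])
        parts = [np.sort(np.concatenate(p)) for p in (train, val, test)]
        if all(p.size for p in parts):
            return tuple(parts)  # type: ignore[return-value]
    raise DataError("could not produce a stratified split with all classes present")


def _fit_xgb(
    X: np.ndarray, y01: np.ndarray, depth: int, cfg: ProtocolConfig, seed: int
) -> xgb.XGBClassifier:
    model = xgb.XGBClassifier(
        max_depth=int(depth),
        n_estimators=cfg.n_boost_rounds,
        learning_rate=cfg.learning_rate,
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
        base_score=0.5,
    )
    model.fit(X, y01)
    return model


def _fit_linear(
    X: np.ndarray, y01: np.ndarray, C: float, algorithm: str
) -> LogisticRegression:
    # lasso = pure L1, ridge = pure L2 (the standard convention)
    model = LogisticRegression(
        l1_ratio=1.0 if algorithm == "lasso" else 0.0,
        C=C, solver="liblinear", max_iter=2000,
    )
    model.fit(X, y01)
    return model


def tune_and_train(
    train_X: np.ndarray,
    train_y: Sequence,
    val_X: np.ndarray,
    val_y: Sequence,
    cfg: ProtocolConfig,
    algorithm: str = "xgboost",
    feature_names: Sequence[str] | None = None,
    repeat_index: int = 0,
) -> FittedModel:
    """Grid-search one hyper-parameter on validation F1, refit on train+val.

    XGBoost tunes the maximum tree depth; lasso/ridge tune the inverse
    penalty weight C on a logarithmic grid. Ties go to the simplest model
    (smallest depth, strongest penalty).
    """
    if algorithm not in {"xgboost", "lasso", "ridge"}:
        raise ConfigError(f"unknown algorithm {algorithm!r}")
    train_y = np.asarray(train_y, dtype=object).astype(str)
    val_y = np.asarray(val_y, dtype=object).astype(str)
    if np.unique(train_y).size < 2:
        raise DataError("degenerate training labels: only one class present")
    feature_names = list(
        feature_names
        if feature_names is not None
        else (f"f{i}" for i in range(np.asarray(train_X).shape[1]))
    )
    y_train01 = (train_y == cfg.pos_label).astype(int)
    y_val_pos = val_y == cfg.pos_label
    fit_seed = int(
        _derive_seed(cfg.seed, repeat_index, salt=101).integers(0, 2**31 - 1)
    )

    def _val_f1(model) -> float:
        classes = list(model.classes_)
        pred = model.predict_proba(val_X)[:, classes.index(1)] >= 0.5
        counts = one_vs_all_counts(y_val_pos, pred, True)
        f1 = metrics_from_counts(counts)["F1"]
        return -1.0 if f1 is None else f1

    best_param, best_f1 = None, -np.inf
    if algorithm == "xgboost":
        grid = cfg.depth_grid  # ascending: first best wins -> smallest depth
        fit = lambda p: _fit_xgb(train_X, y_train01, p, cfg, fit_seed)
    else:
        grid = tuple(sorted(cfg.c_grid))  # ascending C: strongest penalty first
        fit = lambda p: _fit_linear(train_X, y_train01, p, algorithm)
    for p in grid:
        f1 = _val_f1(fit(p))
        if f1 > best_f1:
            best_param, best_f1 = p, f1

    # Final model sees train + validation under the chosen hyper-parameter.
    full_X = np.vstack([train_X, val_X])
    full_y01 = np.concatenate([y_train01, (val_y == cfg.pos_label).astype(int)])
    if algorithm == "xgboost":
        final = _fit_xgb(full_X, full_y01, best_param, cfg, fit_seed)
    else:
        final = _fit_linear(full_X, full_y01, best_param, algorithm)
    return FittedModel(
        algorithm=algorithm,
        model=final,
        chosen_param=float(best_param),
        feature_names=feature_names,
    )


def repeated_protocol(
    features: FeatureMatrix,
    labels: Sequence,
    cfg: ProtocolConfig,
    algorithm: str = "xgboost",
) -> RepeatedRunResult:
    """Run the full repeated hold-out protocol for one cell type.

    ``labels`` is parallel to ``features.sample_ids`` (masked samples are
    dropped together with their labels before splitting). One classifier is
    trained per repeat; with all cell types driven separately the total
    classifier count is ``n_repeats * n_cell_types``.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != len(features.sample_ids):
        raise DataError("one label per sample required")
    keep = ~features.missing_mask
    X_all = features.values[keep]
    y_all = labels[keep].astype(str)
    if np.unique(y_all).size < 2:
        raise DataError("both outcome classes required after masking")

    rows = []
    importance_records: list[dict[str, float]] = []
    for r in range(cfg.n_repeats):
        tr, va, te = split_holdout(y_all, cfg, repeat_index=r)
        X_tr, y_tr = X_all[tr], y_all[tr]
        if cfg.smote is not None:
            smote_seed = int(
                _derive_seed(cfg.seed, r, salt=202).integers(0, 2**31 - 1)
            )
            X_tr, y_tr = smote_resample(
                X_tr, y_tr, replace(cfg.smote, seed=smote_seed)
            )
        model = tune_and_train(
            X_tr, y_tr, X_all[va], y_all[va], cfg,
            algorithm=algorithm,
            feature_names=features.feature_names,
            repeat_index=r,
        )
        scores = model.predict_proba_pos(X_all[te])
        pred = scores >= 0.5
        truth_pos = y_all[te] == cfg.pos_label
        counts = one_vs_all_counts(truth_pos, pred, True)
        metrics = metrics_from_counts(counts)
        try:
            auc = auc_score(scores, truth_pos, True)
        except DataError:
            auc = np.nan
        rows.append(
            {
                "repeat": r,
                "SEN": np.nan if metrics["SEN"] is None else metrics["SEN"],
                "SPE": np.nan if metrics["SPE"] is None else metrics["SPE"],
                "F1": np.nan if metrics["F1"] is None else metrics["F1"],
                "AUC": auc,
                "chosen_param": model.chosen_param,
            }
        )
        if algorithm == "xgboost":
            importance_records.append(model.gain_importance())

    return RepeatedRunResult(
        cell_type=features.cell_type,
        algorithm=algorithm,
        per_repeat=pd.DataFrame(rows),
        importance_records=importance_records,
    )


def aggregate_importance(
    runs: Sequence[dict[str, float]], n_repeats: int | None = None
) -> ImportanceSummary:
    """Aggregate per-run gain dictionaries into selection counts + mean gain.

    A feature's selection count is the number of runs in which it was used
    in at least one split; its mean gain averages over those runs only.
    Features never used are absent. Sorted by (selection count, mean gain)
    descending.
    """
    n_repeats = len(runs) if n_repeats is None else n_repeats
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in runs:
        for feat, gain in rec.items():
            sums[feat] = sums.get(feat, 0.0) + gain
            counts[feat] = counts.get(feat, 0) + 1
    table = pd.DataFrame(
        {
            "feature": list(counts),
            "selection_count": [counts[f] for f in counts],
            "mean_gain": [sums[f] / counts[f] for f in counts],
        }
    ).sort_values(
        ["selection_count", "mean_gain"], ascending=False, ignore_index=True
    )
    return ImportanceSummary(table=table, n_repeats=n_repeats)


def stratify_by_median(scores: Sequence[float]) -> np.ndarray:
    """Split samples into 'low'/'high' groups at the cohort median score.

    ``high`` means strictly above the median; ties go to ``low``. The
    grouping is rank-based, so any monotone transform of the scores leaves
    it unchanged. Intended to feed standard survival routines
    (Kaplan-Meier, Cox models) downstream.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.size < 2:
        raise DataError("need at least two samples to stratify")
    if not np.isfinite(s).all():
        raise DataError("scores must be finite")
    if np.ptp(s) == 0:
        raise DataError("all scores identical; no stratification possible")
    med = np.median(s)
    return np.where(s > med, "high", "low").astype(object)
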