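"""Per-cell-type, per-sample feature matrices for survival modelling.

Two feature families are built from annotated cells of one cell type:

- **median features** — per-sample median expression of each signaling
  marker (p features for a p-marker panel);
- **DREMI features** — the DREMI score of every ordered marker pair
  (X -> Y, X != Y), giving p*(p-1) features. Directionality is kept:
  X -> Y and Y -> X are distinct columns.

Samples contributing fewer cells of the type than the DREMI minimum are
*masked*: their rows carry NaN and are flagged, never imputed — fabricating
mutual-information values for absent cells would contaminate the models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix
from .dremi import DremiParams, dremi_score
from .errors import ConfigError, DataError

__all__ = ["FeatureMatrix", "median_features", "dremi_pair_features", "ordered_pairs"]


@dataclass
class FeatureMatrix:
    """Samples x features table for one cell type, with a missing-row mask."""

    cell_type: str
    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray  # True where the sample failed the min-cell rule

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("feature names must be unique")
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise DataError("values shape must be samples x features")
        if self.missing_mask.shape != (len(self.sample_ids),):
            raise DataError("one mask entry per sample required")
        # Masked rows are all-NaN; unmasked rows are fully finite.
        if self.values.size:
            row_finite = np.isfinite(self.values).all(axis=1)
            if (row_finite & self.missing_mask).any() or (
                ~row_finite & ~self.missing_mask
            ).any():
                raise DataError("missing mask inconsistent with NaN rows")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def drop_masked(self) -> "FeatureMatrix":
        keep = ~self.missing_mask
        return FeatureMatrix(
            cell_type=self.cell_type,
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            feature_names=self.feature_names,
            values=self.values[keep],
            missing_mask=self.missing_mask[keep],
        )


def ordered_pairs(signaling: Sequence[str]) -> list[tuple[str, str]]:
    """All directed pairs (X, Y), X != Y, lexicographic in panel order.

    For p markers this yields exactly p*(p-1) pairs, in an order stable
    across runs and cohorts.
    """
    names = list(signaling)
    if len(set(names)) != len(names):
        raise ConfigError("signaling panel contains duplicate markers")
    return [(a, b) for a in names for b in names if a != b]


def _split_by_sample(
    cells: ExpressionMatrix, cell_type: str
) -> tuple[list[str], list[np.ndarray]]:
    if cells.cell_labels is None or cells.sample_ids is None:
        raise DataError("feature engineering needs per-cell labels and sample ids")
    labels = cells.cell_labels.astype(str)
    if cell_type not in set(labels):
        raise DataError(f"unknown cell type {cell_type!r}")
    samples = list(pd.unique(cells.sample_ids))
    type_mask = labels == cell_type
    groups = [np.flatnonzero(type_mask & (cells.sample_ids == s)) for s in samples]
    return [str(s) for s in samples], groups


def median_features(
    cells: ExpressionMatrix,
    cell_type: str,
    signaling: Sequence[str],
) -> FeatureMatrix:
    """Per-sample median expression of each signaling marker for one cell type.

    Even cell counts use the mean-of-middle-two convention. Samples with no
    cells of the type are masked.
    """
    signaling = list(signaling)
    idx = cells.marker_index(signaling)
    sample_ids, groups = _split_by_sample(cells, cell_type)
    values = np.full((len(sample_ids), len(signaling)), np.nan)
    mask = np.zeros(len(sample_ids), dtype=bool)
    for i, rows in enumerate(groups):
        if rows.size == 0:
            mask[i] = True
            continue
        values[i] = np.median(cells.values[np.ix_(rows, idx)], axis=0)
    return FeatureMatrix(
        cell_type=cell_type,
        sample_ids=sample_ids,
        feature_names=signaling,
        values=values,
        missing_mask=mask,
    )


def dremi_pair_features(
    cells: ExpressionMatrix,
    cell_type: str,
    signaling: Sequence[str],
    params: DremiParams = DremiParams(),
) -> FeatureMatrix:
    """DREMI scores of all directed signaling pairs, per sample, one cell type.

    Samples with fewer than ``params.min_cells`` cells of the type are
    masked — too few cells for a stable conditional-density estimate.
    """
    signaling = list(signaling)
    if len(signaling) < 2:
        raise ConfigError("DREMI features need at least two signaling markers")
    pairs = ordered_pairs(signaling)
    idx = cells.marker_index(signaling)
    col_of = {m: idx[j] for j, m in enumerate(signaling)}
    sample_ids, groups = _split_by_sample(cells, cell_type)
    values = np.full((len(sample_ids), len(pairs)), np.nan)
    mask = np.zeros(len(sample_ids), dtype=bool)
    for i, rows in enumerate(groups):
        if rows.size < params.min_cells:
            mask[i] = True
            continue
        sub = cells.values[rows]
        for j, (a, b) in enumerate(pairs):
            res = dremi_score(
                sub[:, col_of[a]], sub[:, col_of[b]], params=params, pair=(a, b)
            )
            values[i, j] = res.score
    return FeatureMatrix(
        cell_type=cell_type,
        sample_ids=sample_ids,
        feature_names=[f"{a}->{b}" for a, b in pairs],
        values=values,
        missing_mask=mask,
    )
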