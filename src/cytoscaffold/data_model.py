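"""Core containers and IO for cell x marker expression data.

The universal currency of the pipeline is the :class:`ExpressionMatrix`:
cells in rows, protein markers in columns, values on the arcsinh scale once
:func:`arcsinh_transform` has been applied. Delimited text (CSV/TSV with a
header row of marker names) and list-mode FCS 3.x are supported on input;
delimited text on output. Two reserved column names, ``__label__`` and
``__sample__``, carry optional per-cell cell-type labels and sample ids in
delimited files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError, ValidationError
from .fcs import read_fcs

__all__ = [
    "ExpressionMatrix",
    "ReferenceDataset",
    "PanelConfig",
    "SurvivalTable",
    "LABEL_COLUMN",
    "SAMPLE_COLUMN",
    "read_expression",
    "write_expression",
    "arcsinh_transform",
    "inverse_arcsinh_transform",
    "harmonize_panels",
    "filter_reference",
]

LABEL_COLUMN = "__label__"
SAMPLE_COLUMN = "__sample__"

#: Months-after-diagnosis cutoff separating short-term (STS, < 60) from
#: long-term (LTS, >= 60) survivors.
SURVIVAL_CUTOFF_MONTHS = 60.0


@dataclass
class ExpressionMatrix:
    """Cells x markers expression table.

    Parameters
    ----------
    values
        2-D float array, one row per cell, one column per marker.
    marker_names
        Unique marker names, one per column.
    cell_labels
        Optional per-cell cell-type labels (length = number of cells).
    sample_ids
        Optional per-cell sample identifiers.
    transformed
        Whether values are already on the arcsinh scale.
    """

    values: np.ndarray
    marker_names: list[str]
    cell_labels: np.ndarray | None = None
    sample_ids: np.ndarray | None = None
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        self.marker_names = [str(m) for m in self.marker_names]
        if len(self.marker_names) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.marker_names)} marker names for "
                f"{self.values.shape[1]} columns"
            )
        dupes = _duplicates(self.marker_names)
        if dupes:
            raise ValidationError(f"duplicate marker names: {sorted(dupes)}")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values contain NaN/Inf")
        for name in ("cell_labels", "sample_ids"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=object)
                if arr.shape != (self.values.shape[0],):
                    raise ValidationError(f"{name} must have one entry per cell")
                setattr(self, name, arr)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, names: Sequence[str]) -> np.ndarray:
        """Column indices of the given markers; raises if any is missing."""
        pos = {m: i for i, m in enumerate(self.marker_names)}
        missing = [m for m in names if m not in pos]
        if missing:
            raise DataError(f"markers not in matrix: {missing}")
        return np.array([pos[m] for m in names], dtype=int)

    def subset_markers(self, names: Sequence[str]) -> "ExpressionMatrix":
        """New matrix restricted (and reordered) to the given markers."""
        idx = self.marker_index(names)
        return replace(self, values=self.values[:, idx], marker_names=list(names))

    def subset_cells(self, mask_or_index: np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to the given boolean mask or index array."""
        idx = np.asarray(mask_or_index)
        return replace(
            self,
            values=self.values[idx],
            cell_labels=None if self.cell_labels is None else self.cell_labels[idx],
            sample_ids=None if self.sample_ids is None else self.sample_ids[idx],
        )

    def rename_markers(self, alias_map: Mapping[str, str]) -> "ExpressionMatrix":
        """Apply a raw-name -> canonical-name map (names not in the map pass through)."""
        new_names = [alias_map.get(m, m) for m in self.marker_names]
        return replace(self, marker_names=new_names)


@dataclass
class ReferenceDataset:
    """An annotated reference: expression matrix with mandatory cell labels."""

    matrix: ExpressionMatrix
    min_cells_filter: int = 0
    cell_type_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.cell_labels is None:
            raise ValidationError("a reference dataset requires per-cell labels")
        if not self.cell_type_counts:
            labels, counts = np.unique(
                self.matrix.cell_labels.astype(str), return_counts=True
            )
            self.cell_type_counts = dict(zip(labels.tolist(), counts.tolist()))

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cell_type_counts)


@dataclass
class PanelConfig:
    """Panel description: which markers phenotype cells vs carry signal.

    Backbone (phenotyping) markers drive clustering and landmark matching;
    signaling markers feed feature engineering. The two sets must be
    disjoint within one analysis.
    """

    backbone_markers: list[str] = field(default_factory=list)
    signaling_markers: list[str] = field(default_factory=list)
    alias_map: dict[str, str] = field(default_factory=dict)
    arcsinh_cofactor: float = 5.0

    def __post_init__(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ConfigError("arcsinh cofactor must be positive")
        overlap = set(self.backbone_markers) & set(self.signaling_markers)
        if overlap:
            raise ConfigError(
                f"markers cannot be both backbone and signaling: {sorted(overlap)}"
            )
        for group in ("backbone_markers", "signaling_markers"):
            names = getattr(self, group)
            dupes = _duplicates(names)
            if dupes:
                raise ConfigError(f"duplicate {group}: {sorted(dupes)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelConfig":
        known = {"backbone_markers", "signaling_markers", "alias_map", "arcsinh_cofactor"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown panel config keys: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass
class SurvivalTable:
    """Sample-level outcome table for the STS/LTS survival task."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"survival table missing column {col!r}")
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        bad = set(t["group"].astype(str)) - {"STS", "LTS"}
        if bad:
            raise ValidationError(f"group labels must be STS/LTS, got {sorted(bad)}")
        if "survival_months" in t.columns:
            months = t["survival_months"].astype(float)
            if (months < 0).any():
                raise ValidationError("survival_months must be non-negative")
            is_lts = t["group"].astype(str).values == "LTS"
            inconsistent = t.loc[
                is_lts != (months.values >= SURVIVAL_CUTOFF_MONTHS), "sample_id"
            ].tolist()
            if inconsistent:
                raise ValidationError(
                    "group label inconsistent with the 60-month rule for samples: "
                    f"{inconsistent}"
                )

    @classmethod
    def read(cls, path: str | Path) -> "SurvivalTable":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        return cls(pd.read_csv(path, sep=sep))

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        mapping = dict(zip(self.table["sample_id"].astype(str), self.table["group"]))
        missing = [s for s in sample_ids if str(s) not in mapping]
        if missing:
            raise DataError(f"samples missing from survival table: {missing}")
        return np.array([mapping[str(s)] for s in sample_ids], dtype=object)


# ---------------------------------------------------------------------------
# IO


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from FCS or delimited text.

    ``format`` is one of ``fcs``/``csv``/``tsv``; if omitted it is inferred
    from the file extension. Values are flagged untransformed.
    """
    path = Path(path)
    if format is None:
        format = {".fcs": "fcs", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower(), "csv"
        )
    format = format.lower()
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "fcs":
        values, names = read_fcs(path)
        return ExpressionMatrix(values=values, marker_names=names, transformed=False)
    if format not in {"csv", "tsv"}:
        raise ConfigError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: file contains 0 cells")
    labels = samples = None
    if LABEL_COLUMN in df.columns:
        labels = df.pop(LABEL_COLUMN).astype(str).to_numpy(dtype=object)
    if SAMPLE_COLUMN in df.columns:
        samples = df.pop(SAMPLE_COLUMN).astype(str).to_numpy(dtype=object)
    dupes = _duplicates(list(df.columns))
    if dupes:
        raise ValidationError(f"duplicate marker names in {path}: {sorted(dupes)}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValidationError(
                f"{path}: non-numeric value at row {row}, column {col!r}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = numeric
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        marker_names=[str(c) for c in df.columns],
        cell_labels=labels,
        sample_ids=samples,
        transformed=False,
    )


def write_expression(m: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    """Write to delimited text; labels/sample ids go to the reserved columns."""
    df = pd.DataFrame(m.values, columns=m.marker_names)
    if m.cell_labels is not None:
        df[LABEL_COLUMN] = m.cell_labels
    if m.sample_ids is not None:
        df[SAMPLE_COLUMN] = m.sample_ids
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Transforms and harmonization


def arcsinh_transform(
    m: ExpressionMatrix, cofactor: float = 5.0, force: bool = False
) -> ExpressionMatrix:
    """Apply the standard cytometry variance-stabilizing transform.

    Each raw intensity x becomes asinh(x / cofactor). Negative values (bead
    normalization artifacts) are kept as-is; asinh is defined on all reals.
    """
    if cofactor <= 0:
        raise ConfigError("cofactor must be > 0")
    if m.transformed and not force:
        raise DataError(
            "matrix is already arcsinh-transformed (pass force=True to re-apply)"
        )
    return replace(m, values=np.arcsinh(m.values / cofactor), transformed=True)


def inverse_arcsinh_transform(
    m: ExpressionMatrix, cofactor: float = 5.0
) -> ExpressionMatrix:
    """Invert :func:`arcsinh_transform`: x -> sinh(x) * cofactor."""
    if cofactor <= 0:
        raise ConfigError("cofactor must be > 0")
    if not m.transformed:
        raise DataError("matrix is not arcsinh-transformed")
    return replace(m, values=np.sinh(m.values) * cofactor, transformed=False)


def harmonize_panels(
    query: ExpressionMatrix,
    reference: ExpressionMatrix,
    cfg: PanelConfig | None = None,
) -> list[str]:
    """Shared backbone between a query and a reference panel.

    Applies the alias map to both marker lists, intersects them, optionally
    restricts to ``cfg.backbone_markers``, and returns the result in the
    reference panel's order. Matching is exact string match after aliasing:
    silent fuzzy mismatches are worse than loud errors.
    """
    alias = cfg.alias_map if cfg is not None else {}
    q_names = {alias.get(n, n) for n in query.marker_names}
    r_names = [alias.get(n, n) for n in reference.marker_names]
    shared = [n for n in r_names if n in q_names]
    if cfg is not None and cfg.backbone_markers:
        allowed = set(cfg.backbone_markers)
        shared = [n for n in shared if n in allowed]
    if not shared:
        raise DataError("no shared backbone between query and reference panels")
    return shared


def filter_reference(ref: ReferenceDataset, min_cells: int = 300) -> ReferenceDataset:
    """Drop cell types represented by fewer than ``min_cells`` cells.

    The default of 300 keeps only populations with enough cells to yield
    stable landmarks and training examples.
    """
    if min_cells < 1:
        raise ConfigError("min_cells must be >= 1")
    labels = ref.matrix.cell_labels.astype(str)
    keep_types = {t for t, c in ref.cell_type_counts.items() if c >= min_cells}
    if not keep_types:
        raise DataError(
            f"no cell type has >= {min_cells} cells; reference unusable"
        )
    mask = np.array([lab in keep_types for lab in labels])
    return ReferenceDataset(matrix=ref.matrix.subset_cells(mask), min_cells_filter=min_cells)


def _duplicates(names: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for n in names:
        if n in seen:
            dup.add(n)
        seen.add(n)
    return dup


def load_panel_config(path: str | Path) -> PanelConfig:
    """Load a PanelConfig from a YAML or JSON file (block key ``panel`` optional)."""
    import yaml

    path = Path(path)
    try:
        with open(path) as fh:
            if path.suffix.lower() == ".json":
                doc = json.load(fh)
            else:
                doc = yaml.safe_load(fh)
    except Exception as exc:
        raise ConfigError(f"could not parse panel config {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError(f"panel config {path} must be a mapping")
    block = doc.get("panel", doc)
    return PanelConfig.from_dict(block)
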