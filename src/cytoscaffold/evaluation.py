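"""Classification metrics: one-vs-all confusion counts, ACC/SEN/SPE/F1, AUC.

Multiclass problems (cell-type annotation) are scored per class with the
one-vs-all conversion: the class under scrutiny is the positive class, all
other labels pool into the negative class, yielding a 2x2 confusion matrix
per class. Ratios with zero denominators are reported as ``None`` (flagged
undefined) rather than silently zeroed, so that macro averages over rare
classes are not depressed by artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import DataError

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "one_vs_all_counts",
    "metrics_from_counts",
    "auc_score",
    "evaluate_multiclass",
    "evaluate_binary",
]

METRIC_NAMES = ("ACC", "SEN", "SPE", "F1")


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with ``class_label`` as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int
    class_label: str = ""

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise DataError(f"negative count {name}")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def one_vs_all_counts(
    truth: Sequence, predicted: Sequence, class_label: str
) -> ConfusionCounts:
    """Confusion counts treating ``class_label`` as positive, all else negative."""
    t = np.asarray(truth, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if t.shape != p.shape:
        raise DataError("truth and predicted label vectors differ in length")
    tpos = t == class_label
    ppos = p == class_label
    if not tpos.any():
        warnings.warn(
            f"class {class_label!r} absent from truth labels; sensitivity undefined",
            stacklevel=2,
        )
    return ConfusionCounts(
        TP=int(np.sum(tpos & ppos)),
        TN=int(np.sum(~tpos & ~ppos)),
        FP=int(np.sum(~tpos & ppos)),
        FN=int(np.sum(tpos & ~ppos)),
        class_label=class_label,
    )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float | None]:
    """ACC, SEN, SPE and F1 from a 2x2 confusion matrix.

    ACC = (TP+TN)/(TP+TN+FP+FN); SEN = TP/(TP+FN); SPE = TN/(TN+FP);
    F1 = 2TP/(2TP+FP+FN). A metric whose denominator is zero is ``None``.
    """

    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "ACC": _ratio(c.TP + c.TN, c.total),
        "SEN": _ratio(c.TP, c.TP + c.FN),
        "SPE": _ratio(c.TN, c.TN + c.FP),
        "F1": _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
    }


def auc_score(scores: Sequence[float], truth: Sequence, pos_label) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties use midranks."""
    t = np.asarray(truth, dtype=object) == pos_label
    if t.all() or not t.any():
        raise DataError("AUC requires both classes present in truth labels")
    return float(roc_auc_score(t.astype(int), np.asarray(scores, dtype=float)))


@dataclass
class EvalReport:
    """Per-class confusion counts and metrics, plus macro averages."""

    per_class: dict[str, dict] = field(default_factory=dict)
    auc: float | None = None

    @property
    def macro(self) -> dict[str, float | None]:
        """Unweighted mean of each metric over classes where it is defined."""
        out: dict[str, float | None] = {}
        for name in METRIC_NAMES:
            vals = [
                d["metrics"][name]
                for d in self.per_class.values()
                if d["metrics"][name] is not None
            ]
            out[name] = float(np.mean(vals)) if vals else None
        return out

    def to_dict(self) -> dict:
        body = {
            label: {**_counts_dict(d["counts"]), **d["metrics"]}
            for label, d in self.per_class.items()
        }
        return {"per_class": body, "macro": self.macro, "auc": self.auc}


def _counts_dict(c: ConfusionCounts) -> dict[str, int]:
    return {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN}


def evaluate_multiclass(
    truth: Sequence, predicted: Sequence, classes: Sequence[str] | None = None
) -> EvalReport:
    """One-vs-all evaluation over all classes present in the truth labels."""
    t = np.asarray(truth, dtype=object)
    if classes is None:
        classes = sorted({str(x) for x in t})
    report = EvalReport()
    for label in classes:
        counts = one_vs_all_counts(truth, predicted, label)
        report.per_class[label] = {
            "counts": counts,
            "metrics": metrics_from_counts(counts),
        }
    return report


def evaluate_binary(
    truth: Sequence,
    predicted: Sequence,
    pos_label,
    scores: Sequence[float] | None = None,
) -> EvalReport:
    """Binary evaluation with ``pos_label`` positive; AUC if scores given."""
    counts = one_vs_all_counts(truth, predicted, pos_label)
    report = EvalReport(
        per_class={
            str(pos_label): {"counts": counts, "metrics": metrics_from_counts(counts)}
        }
    )
    if scores is not None:
        report.auc = auc_score(scores, truth, pos_label)
    return report
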