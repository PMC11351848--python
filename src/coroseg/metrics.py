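"""Voxel-overlap evaluation: Dice, Jaccard, precision, recall.

All four scores derive from the voxel-level confusion counts between a
predicted binary mask A and a ground-truth mask B:

    DSC = 2|A∩B| / (|A| + |B|) = 2TP / (2TP + FP + FN)
    JI  = |A∩B| / |A∪B|        = TP / (TP + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)

Two masks that are both empty count as perfect agreement (score 1.0) and
the report is flagged, so per-case averaging over cases without the target
structure stays well defined. Metrics are computed per 3D case; multi-case
summaries are unweighted means over cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Tuple

import numpy as np

from .volume import Volume

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "dice",
    "jaccard",
    "precision_recall",
    "evaluate_masks",
]


def _as_binary(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, Volume) else np.asarray(mask)
    if not np.isin(np.unique(data), (0, 1)).all():
        raise ValueError("mask must be binary (values 0/1)")
    return data.astype(bool)


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    dsc: float
    ji: float
    precision: float | None
    recall: float | None
    both_empty: bool = False
    undefined: Tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "dsc": self.dsc,
            "ji": self.ji,
            "precision": self.precision,
            "recall": self.recall,
            "both_empty": self.both_empty,
            "undefined": list(self.undefined),
        }


def confusion_counts(pred, truth) -> Tuple[int, int, int, int]:
    """(tp, fp, fn, tn) voxel counts; an exhaustive partition of the grid."""
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return tp, fp, fn, tn


def dice(pred, truth) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    tp, fp, fn, _ = confusion_counts(pred, truth)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def jaccard(pred, truth) -> float:
    """Jaccard index (intersection over union); 1.0 when both empty."""
    tp, fp, fn, _ = confusion_counts(pred, truth)
    denom = tp + fp + fn
    if denom == 0:
        return 1.0
    return tp / denom


def precision_recall(
    counts: Tuple[int, int, int, int]
) -> Tuple[float | None, float | None]:
    """(precision, recall) from confusion counts; None where undefined."""
    tp, fp, fn, _ = counts
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return precision, recall


def evaluate_masks(pred, truth) -> MetricsReport:
    """Full overlap report for one predicted/truth mask pair."""
    counts = confusion_counts(pred, truth)
    tp, fp, fn, tn = counts
    precision, recall = precision_recall(counts)
    undefined = tuple(
        name
        for name, value in (("precision", precision), ("recall", recall))
        if value is None
    )
    return MetricsReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        dsc=dice(pred, truth),
        ji=jaccard(pred, truth),
        precision=precision,
        recall=recall,
        both_empty=(tp + fp + fn == 0),
        undefined=undefined,
    )


def mean_over_cases(reports: Iterable[MetricsReport]) -> dict:
    """Unweighted per-case mean of DSC/JI/precision/recall."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to aggregate")

    def _mean(values):
        vals = [v for v in values if v is not None]
        return float(np.mean(vals)) if vals else None

    return {
        "dsc": _mean(r.dsc for r in reports),
        "ji": _mean(r.ji for r in reports),
        "precision": _mean(r.precision for r in reports),
        "recall": _mean(r.recall for r in reports),
        "n_cases": len(reports),
    }
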