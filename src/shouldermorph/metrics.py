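"""Segmentation and classification metrics.

Per-class voxel-overlap metrics (Dice, Jaccard, precision, recall) for
segmentation, and confusion-table metrics (accuracy, per-class F1, the
unweighted Macro F1 and the support-weighted Weighted F1) for
classification. Zero-division convention: precision/recall/F1 are 0 when
their denominators vanish, and such entries are flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import LabelVolume

__all__ = [
    "ConfusionTable",
    "MetricsReport",
    "segmentation_metrics",
    "classification_report",
    "paired_metric_test",
]


@dataclass
class ConfusionTable:
    """Rows are truth, columns are prediction; support = row sums."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_predictions(cls, preds, labels, n_classes: int) -> "ConfusionTable":
        preds = np.asarray(preds)
        labels = np.asarray(labels)
        if preds.size == 0:
            raise ValueError("empty input")
        if np.any((preds < 0) | (preds >= n_classes)) or np.any(
            (labels < 0) | (labels >= n_classes)
        ):
            raise ValueError("labels/predictions out of range")
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (labels, preds), 1)
        return cls(counts)


@dataclass
class MetricsReport:
    per_class: pd.DataFrame
    accuracy: float
    macro_f1: float
    weighted_f1: float
    zero_division_hit: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "macro_f1": self.macro_f1,
             "weighted_f1": self.weighted_f1,
             "zero_division_hit": self.zero_division_hit}
        d["per_class"] = self.per_class.to_dict(orient="index")
        d.update(self.extra)
        return d


def _safe_div(num, den):
    num, den = np.asarray(num, float), np.asarray(den, float)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _table_metrics(table: ConfusionTable) -> tuple[pd.DataFrame, float, float, float, bool]:
    counts = table.counts
    tp = np.diag(counts).astype(float)
    pred_tot = counts.sum(axis=0).astype(float)
    true_tot = counts.sum(axis=1).astype(float)
    precision = _safe_div(tp, pred_tot)
    recall = _safe_div(tp, true_tot)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    zero_hit = bool(np.any(pred_tot == 0) or np.any(true_tot == 0)
                    or np.any((precision + recall) == 0))
    accuracy = float(tp.sum() / counts.sum()) if counts.sum() else 0.0
    macro_f1 = float(f1.mean())
    support = true_tot
    weighted_f1 = float((support * f1).sum() / support.sum()) if support.sum() else 0.0
    df = pd.DataFrame({
        "precision": precision, "recall": recall, "f1": f1,
        "support": support.astype(int),
    })
    df.index.name = "class"
    return df, accuracy, macro_f1, weighted_f1, zero_hit


def classification_report(preds, labels, n_classes: int) -> MetricsReport:
    """Accuracy, per-class F1, Macro F1 (equal class weight) and Weighted F1
    (support-weighted) from hard predictions."""
    table = ConfusionTable.from_predictions(preds, labels, n_classes)
    df, acc, macro, weighted, zero_hit = _table_metrics(table)
    return MetricsReport(per_class=df, accuracy=acc, macro_f1=macro,
                         weighted_f1=weighted, zero_division_hit=zero_hit,
                         extra={"confusion": table.counts.tolist()})


def segmentation_metrics(pred: LabelVolume, truth: LabelVolume) -> MetricsReport:
    """Per-class Dice, Jaccard, precision and recall over voxels.

    Foreground summary rows (mean Dice/Jaccard) exclude the background
    class 0.
    """
    p = pred.data if isinstance(pred, LabelVolume) else np.asarray(pred)
    t = truth.data if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    classes = np.union1d(np.unique(p), np.unique(t))
    rows, zero_hit = {}, False
    for c in classes:
        a, b = p == c, t == c
        inter = float((a & b).sum())
        union = float((a | b).sum())
        na, nb = float(a.sum()), float(b.sum())
        dice = 2 * inter / (na + nb) if (na + nb) else 0.0
        jac = inter / union if union else 0.0
        prec = inter / na if na else 0.0
        rec = inter / nb if nb else 0.0
        if na == 0 or nb == 0:
            zero_hit = True
        rows[int(c)] = {"dice": dice, "jaccard": jac, "precision": prec,
                        "recall": rec, "support": int(nb)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "class"
    fg = df.loc[df.index != 0]
    n = p.size
    acc = float((p == t).sum() / n)
    cls_report = classification_report(p.ravel(), t.ravel(), int(classes.max()) + 1)
    return MetricsReport(
        per_class=df, accuracy=acc, macro_f1=cls_report.macro_f1,
        weighted_f1=cls_report.weighted_f1, zero_division_hit=zero_hit,
        extra={
            "mean_foreground_dice": float(fg["dice"].mean()) if len(fg) else 0.0,
            "mean_foreground_jaccard": float(fg["jaccard"].mean()) if len(fg) else 0.0,
        },
    )


def boundary_recall(pred: LabelVolume, truth: LabelVolume) -> float:
    """Mean over foreground classes of the recall on true boundary voxels.

    Boundary voxels are the 6-connectivity class boundaries of the ground
    truth; this emphasises exactly the voxels edge-guided training targets.
    """
    from .celunet import extract_edge_labels

    p = pred.data if isinstance(pred, LabelVolume) else np.asarray(pred)
    t = truth.data if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    edges = extract_edge_labels(truth if isinstance(truth, LabelVolume)
                                else LabelVolume(t, (1, 1, 1))).data
    recalls = []
    for c in np.unique(edges):
        if c == 0:
            continue
        mask = edges == c
        recalls.append(float((p[mask] == c).mean()))
    if not recalls:
        raise ValueError("truth contains no foreground boundary voxels")
    return float(np.mean(recalls))


def paired_metric_test(scores_a, scores_b) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test on per-case metric scores."""
    scores_a, scores_b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if scores_a.shape != scores_b.shape or scores_a.size < 2:
        raise ValueError("need two equal-length score vectors with >= 2 entries")
    if np.allclose(scores_a, scores_b):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(scores_a, scores_b)
    return float(stat), float(p)
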