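"""Imbalanced-classification metrics for residue prediction.

Recall, precision and F1 follow the usual confusion-matrix definitions
with the 0/0 -> 0 convention.  The precision-recall curve is traced over
all distinct score thresholds and its area is computed with the
Davis-Goadrich non-linear interpolation: between two achievable points
the false-positive count is interpolated linearly in the true-positive
count at unit-TP steps, which makes the interpolated precision follow a
hyperbola rather than a straight line.  The curve is anchored at recall 0
with the precision of the earliest achievable point (one true positive),
so a perfect ranking scores 1 and random scores approach the positive
prevalence.

The Wilcoxon signed-rank test compares paired per-chain (or per-fold)
performance statistics of two methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "recall_precision_f1",
    "PrCurve",
    "pr_curve_auc",
    "wilcoxon_signed_rank",
    "top_k_ranking_eval",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """2x2 counts from aligned boolean mappings or arrays.

    Mappings must share exactly the same residue keys; arrays must have
    equal length.
    """
    if hasattr(predicted, "keys") and hasattr(truth, "keys"):
        if set(predicted.keys()) != set(truth.keys()):
            raise ValueError("predicted and true labels cover different residues")
        keys = sorted(predicted.keys())
        pred = np.array([bool(predicted[k]) for k in keys])
        true = np.array([bool(truth[k]) for k in keys])
    else:
        pred = np.asarray(predicted, dtype=bool)
        true = np.asarray(truth, dtype=bool)
        if pred.shape != true.shape:
            raise ValueError("predicted and true label arrays differ in length")
    return ConfusionCounts(
        tp=int((pred & true).sum()),
        fp=int((pred & ~true).sum()),
        tn=int((~pred & ~true).sum()),
        fn=int((~pred & true).sum()),
    )


def recall_precision_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = harmonic mean.

    Zero denominators yield 0 by convention.
    """
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return recall, precision, f1


@dataclass
class PrCurve:
    recall: np.ndarray
    precision: np.ndarray
    area: float


def pr_curve_auc(scores, truth) -> PrCurve:
    """Precision-recall curve and its Davis-Goadrich area.

    ``scores`` are continuous (higher = more binding-like); ``truth`` is
    boolean.  Tied scores share a threshold.  Requires at least one
    positive and one negative example.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("PR curve needs both classes in the ground truth")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    # distinct-threshold points: cumulative TP/FP after each tie group
    boundaries = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], int)
    idx = np.concatenate([boundaries, [len(s) - 1]])
    cum_tp = np.cumsum(t)[idx]
    cum_fp = np.cumsum(~t)[idx]

    # Davis-Goadrich: interpolate FP linearly in TP at unit-TP steps
    pts: list[tuple[float, float]] = []  # (TP, FP), floats
    prev_tp, prev_fp = 0.0, 0.0
    for tp, fp in zip(cum_tp, cum_fp):
        tp, fp = float(tp), float(fp)
        if tp > prev_tp:
            slope = (fp - prev_fp) / (tp - prev_tp)
            x = prev_tp + 1.0
            while x < tp - 1e-12:
                pts.append((x, prev_fp + slope * (x - prev_tp)))
                x += 1.0
        pts.append((tp, fp))
        prev_tp, prev_fp = tp, fp

    curve = [(tp, fp) for tp, fp in pts if tp >= 1.0]
    rec = np.array([tp / n_pos for tp, _ in curve])
    prec = np.array([tp / (tp + fp) for tp, fp in curve])
    # anchor at recall 0 with the earliest achievable precision
    rec = np.concatenate([[0.0], rec])
    prec = np.concatenate([[prec[0]], prec])
    area = float(np.trapezoid(prec, rec))
    return PrCurve(recall=rec, precision=prec, area=area)


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired statistics.

    Exact null distribution for small samples without ties; normal
    approximation with tie correction otherwise (scipy's ``auto`` mode).
    All-zero differences return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    if np.count_nonzero(diffs) < 6:
        warnings.warn("fewer than 6 non-zero differences; p-value is weakly informative")
    res = scipy.stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
    return float(res.pvalue)


def top_k_ranking_eval(
    scores: dict, true_binding: set, k: int
) -> tuple[float, float, list]:
    """Take the k highest-scoring surface residues as predicted binders.

    Ties are broken by ascending sequence index.  Returns (recall,
    precision, predicted_keys).  When k equals the number of true
    binders, recall and precision coincide.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(scores):
        raise ValueError(f"k = {k} exceeds the {len(scores)} scored residues")
    ranked = sorted(scores, key=lambda key: (-scores[key], key[1], key[2], key[0]))
    predicted = ranked[:k]
    tp = sum(1 for key in predicted if key in true_binding)
    recall = tp / len(true_binding) if true_binding else 0.0
    precision = tp / k
    return recall, precision, predicted
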