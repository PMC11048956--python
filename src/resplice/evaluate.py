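"""Confusion-matrix metrics, ROC/AUC, and cross-organism evaluation.

The positive class is the splice site throughout; predicted labels are the
argmax of the 2-way softmax (equivalent to a 0.5 probability threshold).
Metrics follow the standard confusion-matrix definitions:

    Acc = (TP+TN)/(TP+TN+FP+FN)   Pre = TP/(TP+FP)   Sn = TP/(TP+FN)
    Sp  = TN/(TN+FP)              F1  = 2TP/(2TP+FP+FN)   Err = 1 - Acc

A metric with a zero denominator is reported as undefined (``None``) rather
than silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "roc_points_to_csv",
    "evaluate_model",
    "cross_organism_eval",
]


class EvalError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise EvalError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Fractions in [0, 1]; ``None`` marks an undefined (0/0) metric.
    ``as_percent`` renders a percentage table row (2 decimals)."""

    acc: float | None
    pre: float | None
    sn: float | None
    sp: float | None
    f1: float | None
    err: float | None
    auc: float | None = None
    train_tag: str | None = None
    test_tag: str | None = None

    def as_percent(self) -> dict[str, str]:
        out = {}
        for name in ("acc", "pre", "sn", "sp", "err", "f1", "auc"):
            v = getattr(self, name)
            out[name] = "undefined" if v is None else f"{100 * v:.2f}"
        return out


def confusion(labels: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Counts with label 1 = splice site (positive class)."""
    y = np.asarray(labels)
    p = np.asarray(predicted)
    if y.shape != p.shape:
        raise EvalError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts, auc: float | None = None,
            train_tag: str | None = None, test_tag: str | None = None) -> MetricsReport:
    """Confusion-derived metrics; AUC is supplied separately (from scores)."""
    if counts.total == 0:
        raise EvalError("cannot compute metrics on an empty sample")
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    acc = _ratio(tp + tn, counts.total)
    return MetricsReport(
        acc=acc,
        pre=_ratio(tp, tp + fp),
        sn=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        err=None if acc is None else 1.0 - acc,
        auc=auc,
        train_tag=train_tag,
        test_tag=test_tag,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney statistic; ties count half) and ROC curve points.

    ``scores`` are positive-class probabilities; returns ``(auc, points)``
    with points as an (n, 2) array of (FPR, TPR) along the curve.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise EvalError("scores and labels must have equal length")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvalError("AUC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def roc_points_to_csv(path, points: np.ndarray) -> None:
    """Write ROC curve points as CSV (fpr, tpr) for plotting."""
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in np.asarray(points):
            fh.write(f"{fpr:.6f},{tpr:.6f}\n")


def evaluate_model(network, X: np.ndarray, Y: np.ndarray,
                   train_tag: str | None = None,
                   test_tag: str | None = None,
                   batch_size: int = 256) -> MetricsReport:
    """Standard evaluation of a trained network on an encoded split.

    ``Y`` is the one-hot label matrix ([1,0] = splice site). Returns the
    full metrics report including AUC from the softmax site probability.
    """
    probs = np.concatenate([
        network.predict_proba(X[i : i + batch_size])
        for i in range(0, len(X), batch_size)
    ])
    labels = (Y[:, 0] == 1).astype(int)  # column 0 is the site class
    predicted = (probs[:, 0] >= probs[:, 1]).astype(int)
    counts = confusion(labels, predicted)
    auc, _ = roc_auc(probs[:, 0], labels)
    return metrics(counts, auc=auc, train_tag=train_tag, test_tag=test_tag)


def cross_organism_eval(network, test_split, train_tag: str = "A",
                        test_tag: str = "B") -> MetricsReport:
    """Evaluate a model trained on organism A on organism B's test split.

    ``test_split`` is either an encoded ``(X, Y)`` pair or a
    :class:`~resplice.datasets.DatasetSplits` (its test partition is used).
    Both datasets must share the window geometry; a length mismatch is an
    error, not a silent reshape.
    """
    from .datasets import DatasetSplits, encode_splits

    if isinstance(test_split, DatasetSplits):
        X, Y = encode_splits(test_split)["test"]
    else:
        X, Y = test_split
    expected = network.spec.window_length
    if X.shape[1] != expected:
        raise EvalError(
            f"window length mismatch: model expects {expected}, data has {X.shape[1]}"
        )
    return evaluate_model(network, X, Y, train_tag=train_tag, test_tag=test_tag)
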