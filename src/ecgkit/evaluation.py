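"""Confusion-matrix construction and classification metrics.

Accuracy, precision, and recall follow the usual one-vs-rest reductions
(accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP), recall =
TP/(TP+FN)); multiclass accuracy is additionally reported as trace/n.
Zero-denominator metrics return 0 and are flagged, never raised — small
synthetic folds can miss a class entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "EvalReport", "confusion", "metrics",
           "plot_confusion"]


@dataclass
class ConfusionCounts:
    """Full C x C count matrix plus per-class one-vs-rest reductions."""

    matrix: np.ndarray  # matrix[i, j] = #(truth i, predicted j)
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]


def confusion(pred, truth, n_classes: int) -> ConfusionCounts:
    """Tally counts; ``matrix[i][j]`` counts truth i predicted as j."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.size} vs {truth.size}")
    if pred.size and (pred.max() >= n_classes or truth.max() >= n_classes
                      or pred.min() < 0 or truth.min() < 0):
        raise ValueError(f"class ids must lie in [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (truth, pred), 1)
    tp = np.diag(m).astype(np.int64)
    fn = m.sum(axis=1) - tp
    fp = m.sum(axis=0) - tp
    tn = m.sum() - tp - fn - fp
    return ConfusionCounts(matrix=m, tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class EvalReport:
    accuracy: float  # multiclass: trace/n
    ovr_accuracy: list  # per-class (TP+TN)/(TP+TN+FP+FN)
    precision: list
    recall: list
    f1: list
    macro_precision: float
    macro_recall: float
    macro_f1: float
    support: list
    normalized_matrix: list  # rows sum to 1; zero-support rows flagged
    zero_division_flags: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _safe_div(num, den, flags, what):
    out = np.zeros_like(np.asarray(num, dtype=np.float64))
    den = np.asarray(den, dtype=np.float64)
    ok = den > 0
    out[ok] = np.asarray(num, dtype=np.float64)[ok] / den[ok]
    for c in np.flatnonzero(~ok):
        flags.append(f"{what}[{c}]: zero denominator")
    return out


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Derive the evaluation report from confusion counts."""
    if counts.n < 1:
        raise ValueError("need at least one sample")
    m = counts.matrix.astype(np.float64)
    flags: list[str] = []
    precision = _safe_div(counts.tp, counts.tp + counts.fp, flags, "precision")
    recall = _safe_div(counts.tp, counts.tp + counts.fn, flags, "recall")
    f1 = np.zeros_like(precision)
    pr = precision + recall
    nz = pr > 0
    f1[nz] = 2 * precision[nz] * recall[nz] / pr[nz]
    for c in np.flatnonzero(~nz):
        flags.append(f"f1[{c}]: zero denominator")
    ovr_acc = (counts.tp + counts.tn) / counts.n
    support = m.sum(axis=1)
    norm = np.zeros_like(m)
    for i, s in enumerate(support):
        if s > 0:
            norm[i] = m[i] / s
        else:
            flags.append(f"normalized_matrix[{i}]: zero support")
    return EvalReport(
        accuracy=float(np.trace(m) / counts.n),
        ovr_accuracy=ovr_acc.tolist(),
        precision=precision.tolist(),
        recall=recall.tolist(),
        f1=f1.tolist(),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        support=support.tolist(),
        normalized_matrix=norm.tolist(),
        zero_division_flags=flags,
    )


def plot_confusion(counts: ConfusionCounts, class_names=None, path=None,
                   normalized: bool = True):
    """Render the (optionally row-normalized) confusion matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = counts.matrix.astype(np.float64)
    if normalized:
        sums = m.sum(axis=1, keepdims=True)
        m = np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(m, cmap="Blues", vmin=0)
    C = counts.n_classes
    names = class_names or [str(i) for i in range(C)]
    ax.set_xticks(range(C), names)
    ax.set_yticks(range(C), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(C):
        for j in range(C):
            ax.text(j, i, f"{m[i, j]:.2f}" if normalized else f"{int(m[i, j])}",
                    ha="center", va="center",
                    color="white" if m[i, j] > m.max() / 2 else "black")
    fig.colorbar(im)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
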