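"""Multi-class evaluation: confusion matrix and the four summary figures.

Accuracy, precision, sensitivity (recall / true-positive rate) and
specificity (true-negative rate) are computed one-vs-rest per class and
macro-averaged over the classes actually present in the true labels;
micro averaging is available as an option.  Classes whose denominator is
zero (e.g. never predicted, so TP+FP = 0) are skipped in the macro mean
rather than scored zero — a small test split should not be penalized for
classes it simply does not contain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ecg_io import CLASS_LABELS

__all__ = ["ConfusionMatrix", "confusion", "summarize", "metrics_table"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i, j] = number of samples of true class i predicted as j."""

    counts: np.ndarray
    label_vocabulary: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        k = len(self.label_vocabulary)
        if c.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels,
    predicted_labels,
    label_vocabulary: tuple[str, ...] = CLASS_LABELS,
) -> ConfusionMatrix:
    """Tally a confusion matrix from two equal-length label sequences."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    index = {s: i for i, s in enumerate(label_vocabulary)}
    counts = np.zeros((len(label_vocabulary),) * 2, dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside vocabulary: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(label_vocabulary))


def summarize(cm: ConfusionMatrix, average: str = "macro") -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity from a confusion matrix.

    ``average`` is ``"macro"`` (mean of one-vs-rest scores over classes
    present in the true labels, zero-denominator classes skipped) or
    ``"micro"`` (pooled counts over the same classes).
    """
    if average not in ("macro", "micro"):
        raise ValueError(f"average must be 'macro' or 'micro', got {average!r}")
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c).astype(float)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = total - tp - fn - fp
    present = c.sum(axis=1) > 0

    if average == "micro":
        m = present
        precision = _ratio(tp[m].sum(), (tp + fp)[m].sum())
        sensitivity = _ratio(tp[m].sum(), (tp + fn)[m].sum())
        specificity = _ratio(tn[m].sum(), (tn + fp)[m].sum())
    else:
        precision = _macro(tp, tp + fp, present)
        sensitivity = _macro(tp, tp + fn, present)
        specificity = _macro(tn, tn + fp, present)
    return {
        "accuracy": float(tp.sum() / total),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }


def _ratio(num: float, den: float) -> float:
    return float(num / den) if den > 0 else float("nan")

def _macro(num: np.ndarray, den: np.ndarray, present: np.ndarray) -> float:
    keep = present & (den > 0)
    if not keep.any():
        return float("nan")
    return float(np.mean(num[keep] / den[keep]))


def metrics_table(results: dict[str, dict[str, float]]) -> str:
    """Human-readable metric x condition table.

    ``results`` maps a column name (e.g. ``"aligned/10"``) to a metrics
    dict from :func:`summarize`.
    """
    metrics = ["accuracy", "precision", "sensitivity", "specificity"]
    cols = list(results)
    widths = [max(len(c), 6) for c in cols]
    head = f"{'Metric':<12}" + "  ".join(f"{c:>{w}}" for c, w in zip(cols, widths))
    lines = [head, "-" * len(head)]
    for m in metrics:
        row = f"{m.capitalize():<12}" + "  ".join(
            f"{results[c][m]:>{w}.3f}" for c, w in zip(cols, widths)
        )
        lines.append(row)
    return "\n".join(lines)


def save_metrics(metrics: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(metrics, indent=2))
    return path
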