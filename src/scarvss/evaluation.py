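"""Confusion matrices and ordinal tolerance accuracy.

Because VSS totals are ordinal, accuracy is reported at three tolerance
levels: *exact* (the predicted class equals the true one), *one-score
tolerance* and *two-score tolerance*.  Tolerance is measured in POSITIONS
within the ascending list of observed classes: with observed totals
(0, 1, 2, 4, 5, 7, 8, 9), predicting 5 for a true 4 is one position off
even though the raw score difference is 1, and predicting 7 for a true 5
is also one position off although the scores differ by 2.  A raw
score-difference variant (``mode="score"``) is available behind a flag.

Percentages are rounded half-up to two decimals.

Two reference confusion matrices from published LOO runs on the original
scar photographs ship as worked examples: the ECOC-OSVM run on
(LBP+SV)+(RGB+HSV+Lab) features and the ECOC-kNN run on
(LBP+SV+GLCM)+(RGB+HSV+Lab) features.  They make the tolerance-accuracy
arithmetic reproducible without any image data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts grid with rows = true class, columns = predicted class,
    both ordered by ascending class label."""

    class_order: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        K = self.class_order.size
        if self.counts.shape != (K, K):
            raise ValueError("counts grid does not match class_order")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(true, pred, class_order=None) -> ConfusionMatrix:
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise ValueError("true and predicted label sequences differ in length")
    if class_order is None:
        class_order = np.unique(np.concatenate([true, pred]))
    else:
        class_order = np.asarray(class_order)
        known = set(class_order.tolist())
        unknown = [x for x in np.unique(np.concatenate([true, pred])) if x not in known]
        if unknown:
            raise ValueError(f"labels {unknown} not in class_order")
    index = {c: k for k, c in enumerate(class_order.tolist())}
    K = class_order.size
    counts = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(true, pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(class_order=class_order, counts=counts)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def tolerance_accuracy(cm: ConfusionMatrix, tol: int, mode: str = "index") -> float:
    """Percentage of predictions within ``tol`` of the true class.

    ``mode="index"`` (default) measures distance in positions within the
    ordered class list; ``mode="score"`` measures the absolute difference
    of the raw class labels.  Returns 100 * accepted / total rounded
    half-up to 2 decimals.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    K = cm.class_order.size
    if mode == "index":
        idx = np.arange(K)
        dist = np.abs(idx[:, None] - idx[None, :])
    elif mode == "score":
        scores = cm.class_order.astype(np.float64)
        dist = np.abs(scores[:, None] - scores[None, :])
    else:
        raise ValueError(f"unknown tolerance mode {mode!r}")
    accepted = int(cm.counts[dist <= tol].sum())
    return _round2(100.0 * accepted / cm.total)


def evaluation_report(cm: ConfusionMatrix, mode: str = "index") -> dict:
    """Exact / one-score / two-score accuracies, per-class recall and the
    labeled matrix, as a JSON-serializable record."""
    row_sums = cm.counts.sum(axis=1)
    recall = {
        int(c): (float(cm.counts[k, k] / row_sums[k]) if row_sums[k] else None)
        for k, c in enumerate(cm.class_order.tolist())
    }
    return {
        "classes": [int(c) for c in cm.class_order.tolist()],
        "counts": cm.counts.tolist(),
        "n": cm.total,
        "tolerance_mode": mode,
        "exact": tolerance_accuracy(cm, 0, mode),
        "one_score": tolerance_accuracy(cm, 1, mode),
        "two_score": tolerance_accuracy(cm, 2, mode),
        "per_class_recall": recall,
    }


def render_report(report: dict) -> str:
    lines = [
        f"exact accuracy:                {report['exact']:.2f} %",
        f"one-score tolerance accuracy:  {report['one_score']:.2f} %",
        f"two-score tolerance accuracy:  {report['two_score']:.2f} %",
        f"samples: {report['n']}   tolerance mode: {report['tolerance_mode']}",
        "",
        "confusion matrix (rows: true, columns: predicted)",
    ]
    classes = report["classes"]
    header = "true\\pred " + " ".join(f"{c:>5d}" for c in classes)
    lines.append(header)
    for c, row in zip(classes, report["counts"]):
        lines.append(f"{c:>9d} " + " ".join(f"{v:>5d}" for v in row))
    lines.append("")
    lines.append("per-class recall: " + "  ".join(
        f"{c}:{r:.3f}" if r is not None else f"{c}:n/a"
        for c, r in report["per_class_recall"].items()
    ))
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def write_confusion_csv(cm: ConfusionMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("true\\pred," + ",".join(str(int(c)) for c in cm.class_order) + "\n")
        for c, row in zip(cm.class_order, cm.counts):
            fh.write(str(int(c)) + "," + ",".join(str(int(v)) for v in row) + "\n")


def read_confusion_csv(path) -> ConfusionMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"confusion matrix file {path}: too few rows")
    header = lines[0].split(",")[1:]
    try:
        class_order = np.array([int(x) for x in header])
        rows = []
        row_labels = []
        for ln in lines[1:]:
            parts = ln.split(",")
            row_labels.append(int(parts[0]))
            rows.append([int(x) for x in parts[1:]])
    except ValueError:
        raise ValueError(f"confusion matrix file {path}: non-integer entries") from None
    counts = np.array(rows, dtype=np.int64)
    if row_labels != class_order.tolist():
        raise ValueError(f"confusion matrix file {path}: row labels do not match header")
    return ConfusionMatrix(class_order=class_order, counts=counts)


# --------------------------------------------------------------------------
# Packaged worked examples: published LOO confusion matrices on the
# original 216 scar sub-images (classes = observed VSS totals).

_SCAR_CLASSES = np.array([0, 1, 2, 4, 5, 7, 8, 9])

#: ECOC with Bayesian-optimized SVM learners on (LBP+SV)+(RGB+HSV+Lab).
_OSVM_COMBINED = np.array(
    [
        [20, 5, 1, 0, 1, 0, 0, 0],
        [4, 74, 1, 0, 2, 0, 0, 0],
        [0, 1, 17, 0, 0, 0, 0, 0],
        [0, 0, 1, 8, 0, 0, 0, 0],
        [0, 0, 0, 0, 9, 0, 0, 0],
        [0, 1, 0, 0, 0, 36, 2, 6],
        [0, 0, 0, 0, 0, 1, 8, 0],
        [0, 0, 0, 0, 0, 6, 0, 12],
    ],
    dtype=np.int64,
)

#: ECOC with 1-NN learners on (LBP+SV+GLCM)+(RGB+HSV+Lab).
_KNN_COMBINED = np.array(
    [
        [18, 5, 2, 1, 1, 0, 0, 0],
        [3, 75, 1, 2, 0, 0, 0, 0],
        [0, 5, 13, 0, 0, 0, 0, 0],
        [0, 0, 0, 9, 0, 0, 0, 0],
        [2, 0, 0, 0, 7, 0, 0, 0],
        [2, 4, 0, 0, 1, 27, 6, 5],
        [0, 0, 0, 0, 0, 0, 9, 0],
        [0, 1, 0, 0, 0, 5, 0, 12],
    ],
    dtype=np.int64,
)

REFERENCE_CONFUSIONS = {
    "osvm_combined": ConfusionMatrix(_SCAR_CLASSES, _OSVM_COMBINED),
    "knn_combined": ConfusionMatrix(_SCAR_CLASSES, _KNN_COMBINED),
}


def reference_confusion(name: str) -> ConfusionMatrix:
    """Fetch a packaged worked-example confusion matrix by name
    (``osvm_combined`` or ``knn_combined``)."""
    try:
        return REFERENCE_CONFUSIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown reference matrix {name!r}; choose from "
            f"{sorted(REFERENCE_CONFUSIONS)}"
        ) from None
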