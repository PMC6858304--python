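"""Classifier and counting evaluation: confusion matrices, one-vs-rest
precision/recall, and Pearson correlation of predicted vs true counts with
Fisher-z confidence intervals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["ConfusionMatrix", "confusion", "precision_recall",
           "count_correlation", "CorrelationResult"]


@dataclass
class ConfusionMatrix:
    """Rows are truth, columns are predictions."""

    counts: np.ndarray
    classes: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def row(self, cls) -> np.ndarray:
        return self.counts[self.classes.index(cls)]


def confusion(truth, predicted, classes=None) -> ConfusionMatrix:
    """Count-based confusion matrix over the union of observed classes (or
    an explicit class list); accuracy is trace over total."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValidationError(
            f"label sequences differ in length: {truth.shape} vs "
            f"{predicted.shape}")
    if classes is None:
        classes = sorted(set(truth.tolist()) | set(predicted.tolist()))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def precision_recall(cm: ConfusionMatrix, cls) -> tuple[float | None,
                                                        float | None]:
    """One-vs-rest precision and recall for ``cls``.

    precision = TP / (TP + FP); recall = TP / (TP + FN). A zero denominator
    yields ``None`` (undefined), never 0.
    """
    if cls not in cm.classes:
        raise ValidationError(f"class {cls!r} not in matrix classes")
    i = cm.classes.index(cls)
    tp = float(cm.counts[i, i])
    fp = float(cm.counts[:, i].sum() - tp)
    fn = float(cm.counts[i, :].sum() - tp)
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return precision, recall


@dataclass
class CorrelationResult:
    r: float | None
    ci95: tuple[float, float] | None
    p: float | None
    n: int


def _pearson_with_ci(pred: np.ndarray, true: np.ndarray) -> CorrelationResult:
    n = len(pred)
    if np.std(pred) == 0 or np.std(true) == 0:
        return CorrelationResult(r=None, ci95=None, p=None, n=n)
    r, p = stats.pearsonr(pred, true)
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959963984540054 * se)),
              float(np.tanh(z + 1.959963984540054 * se)))
    else:
        ci = (float(r), float(r))
    return CorrelationResult(r=float(r), ci95=ci, p=float(p), n=n)


def count_correlation(results) -> dict[str, CorrelationResult]:
    """Pearson r (with Fisher-z 95% CI and two-sided p) of predicted vs
    true counts, per phenotype, across a list of
    :class:`~netquant.quantify.CountResult`.

    Requires at least 3 result pairs with ground truth; a zero-variance
    vector flags the correlation undefined (``r=None``).
    """
    pairs = [(r.predicted, r.truth) for r in results if r.truth is not None]
    if len(pairs) < 3:
        raise ValidationError("need at least 3 paired counts")
    pred = np.asarray([p for p, _ in pairs], dtype=float)
    true = np.asarray([t for _, t in pairs], dtype=float)
    return {"non_netotic": _pearson_with_ci(pred[:, 0], true[:, 0]),
            "netotic": _pearson_with_ci(pred[:, 1], true[:, 1])}
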