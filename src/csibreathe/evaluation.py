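"""Confusion-matrix evaluation and cross-validation.

Convention used throughout (note it is the transpose of scikit-learn's):
rows of the confusion matrix are the *predicted* class, columns the *true*
class. For class r with matrix C and N = sum(C):

    TP_r = C_rr                   FP_r = sum_{i != r} C_ri   (row minus diag)
    FN_r = sum_{i != r} C_ir      TN_r = N - TP_r - FP_r - FN_r

    accuracy    = trace(C) / N
    precision_r = C_rr / sum_i C_ri
    recall_r    = C_rr / sum_i C_ir
    specificity_r = TN_r / (TN_r + FP_r)
    F1_r        = 2 precision_r recall_r / (precision_r + recall_r)

Macro metrics are arithmetic means of the per-class values. Classes with a
zero denominator get metric 0 and a logged warning.

Cross-validation uses a seeded shuffle and stratified near-equal folds:
every sample appears in exactly one test fold and k-1 training folds. Both
across-fold and binomial 95% intervals are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "ClassCounts",
    "class_counts",
    "MetricsReport",
    "metrics",
    "stratified_folds",
    "CrossValidationResult",
    "kfold_cross_validate",
]


@dataclass
class ConfusionMatrix:
    """R x R counts; rows = predicted class, columns = true class."""

    counts: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(c.dtype, np.integer) and not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        self.counts = c.astype(np.int64)
        if self.labels is None:
            self.labels = np.arange(c.shape[0])

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def percentages(self) -> np.ndarray:
        """Each cell as a percentage of the total evaluated streams."""
        return 100.0 * self.counts / self.total

    def column_normalized(self) -> np.ndarray:
        """Per-true-class percentages (columns sum to 100), as used in
        confusion-matrix heat maps."""
        col = self.counts.sum(axis=0, keepdims=True).astype(float)
        col[col == 0] = 1.0
        return 100.0 * self.counts / col


def confusion_matrix(predicted, truth, n_classes: int | None = None) -> ConfusionMatrix:
    """Build the confusion matrix: counts[i, j] = #{predicted i and true j}."""
    pred = np.asarray(predicted, dtype=np.int64)
    true = np.asarray(truth, dtype=np.int64)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("predicted and truth must be equal-length 1-D label arrays")
    R = int(n_classes) if n_classes is not None else int(max(pred.max(), true.max())) + 1
    if np.any(pred < 0) or np.any(true < 0) or np.any(pred >= R) or np.any(true >= R):
        raise ValueError(f"labels must lie in 0..{R - 1}")
    counts = np.zeros((R, R), dtype=np.int64)
    np.add.at(counts, (pred, true), 1)
    return ConfusionMatrix(counts=counts)


@dataclass(frozen=True)
class ClassCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def class_counts(C, r: int) -> ClassCounts:
    """Per-class TP/FP/FN/TN from a rows=predicted confusion matrix."""
    counts = C.counts if isinstance(C, ConfusionMatrix) else np.asarray(C)
    R = counts.shape[0]
    if not 0 <= r < R:
        raise ValueError(f"class index {r} out of range 0..{R - 1}")
    tp = int(counts[r, r])
    fp = int(counts[r, :].sum() - tp)
    fn = int(counts[:, r].sum() - tp)
    tn = int(counts.sum() - tp - fp - fn)
    return ClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class MetricsReport:
    """Overall accuracy plus per-class and macro-averaged metrics."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_specificity: float
    macro_f1: float
    per_class_counts: list = field(default_factory=list)
    n_total: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_specificity": self.macro_specificity,
            "macro_f1": self.macro_f1,
            "n_total": self.n_total,
        }


def _safe_div(num, den, what, r):
    if den == 0:
        warnings.warn(f"zero denominator for {what} of class {r}; reporting 0")
        return 0.0
    return num / den


def metrics(C) -> MetricsReport:
    """All confusion-matrix metrics (accuracy, per-class and macro P/R/S/F1)."""
    cm = C if isinstance(C, ConfusionMatrix) else ConfusionMatrix(np.asarray(C))
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    R = cm.n_classes
    prec = np.zeros(R)
    rec = np.zeros(R)
    spec = np.zeros(R)
    f1 = np.zeros(R)
    per_cc = []
    for r in range(R):
        cc = class_counts(cm, r)
        per_cc.append(cc)
        prec[r] = _safe_div(cc.tp, cc.tp + cc.fp, "precision", r)
        rec[r] = _safe_div(cc.tp, cc.tp + cc.fn, "recall", r)
        spec[r] = _safe_div(cc.tn, cc.tn + cc.fp, "specificity", r)
        f1[r] = _safe_div(2 * prec[r] * rec[r], prec[r] + rec[r], "F1", r)
    return MetricsReport(
        accuracy=float(np.trace(counts) / total),
        precision=prec,
        recall=rec,
        specificity=spec,
        f1=f1,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_specificity=float(spec.mean()),
        macro_f1=float(f1.mean()),
        per_class_counts=per_cc,
        n_total=total,
    )


def stratified_folds(y, k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified partition into k near-equal folds.

    Samples are shuffled, then dealt class-by-class round-robin with a
    rotating remainder offset so fold sizes differ by at most one overall
    and per-class counts per fold differ by at most one. Supports
    leave-one-out (k = n).
    """
    y = np.asarray(y)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k must not exceed the dataset size")
    rng = np.random.default_rng(seed)
    folds: list[list] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, sample in enumerate(idx):
            folds[(offset + j) % k].append(sample)
        offset = (offset + len(idx)) % k
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


@dataclass
class CrossValidationResult:
    """Per-fold metrics plus dispersion of the overall accuracy."""

    fold_reports: list
    fold_accuracies: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    min_accuracy: float
    max_accuracy: float
    #: across-fold 95% interval (mean +- 1.96 * std / sqrt(k))
    fold_ci95: tuple
    #: binomial normal-approximation 95% interval on the pooled accuracy
    binomial_ci95: tuple
    pooled_confusion: ConfusionMatrix = None
    pooled_report: MetricsReport = None


def kfold_cross_validate(X, y, trainer, k: int = 10, seed: int = 0) -> CrossValidationResult:
    """Stratified k-fold cross-validation with a seeded shuffle.

    ``trainer(X_train, y_train)`` must return a fitted object with a
    ``predict(X)`` method. Each sample is tested exactly once and used for
    training k-1 times. Reports mean, sample standard deviation and the
    min-max interval of overall accuracy across folds, plus both an
    across-fold and a binomial 95% interval.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    folds = stratified_folds(y, k, seed)
    classes = np.unique(y)
    class_index = {c: i for i, c in enumerate(classes)}
    R = len(classes)
    y_idx = np.array([class_index[v] for v in y])

    reports = []
    accs = []
    pooled = np.zeros((R, R), dtype=np.int64)
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        model = trainer(X[mask], y[mask])
        pred = np.asarray(model.predict(X[test_idx]))
        pred_idx = np.array([class_index[v] for v in pred])
        cm = confusion_matrix(pred_idx, y_idx[test_idx], R)
        rep = metrics(cm)
        reports.append(rep)
        accs.append(rep.accuracy)
        pooled += cm.counts
    accs = np.asarray(accs)
    mean = float(accs.mean())
    std = float(accs.std(ddof=1)) if k > 1 else 0.0
    half = 1.96 * std / np.sqrt(k)
    n_total = int(pooled.sum())
    pooled_acc = float(np.trace(pooled) / n_total)
    bin_half = 1.96 * np.sqrt(max(pooled_acc * (1 - pooled_acc), 0.0) / n_total)
    pooled_cm = ConfusionMatrix(pooled, labels=classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled_rep = metrics(pooled_cm)
    return CrossValidationResult(
        fold_reports=reports,
        fold_accuracies=accs,
        mean_accuracy=mean,
        std_accuracy=std,
        min_accuracy=float(accs.min()),
        max_accuracy=float(accs.max()),
        fold_ci95=(mean - half, mean + half),
        binomial_ci95=(pooled_acc - bin_half, pooled_acc + bin_half),
        pooled_confusion=pooled_cm,
        pooled_report=pooled_rep,
    )
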