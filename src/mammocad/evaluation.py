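"""Final classification harness: k-fold CV, confusion-matrix metrics, and a
normal-approximation margin of error.

The classifier registry mirrors common MATLAB Classification Learner
presets with scikit-learn estimators: cubic/quadratic/linear/RBF SVMs,
1-nearest-neighbor ("fine KNN"), and narrow/medium/wide and
bi-/tri-layered feed-forward networks. Metrics are recomputed from the
stored confusion matrix: accuracy, macro-averaged precision, sensitivity,
F1 and false-positive rate, Cohen's kappa (chance-corrected agreement) and
the multi-class Matthews correlation coefficient. All metrics are reported
in percent except FPR, which stays a fraction.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CLASSIFIERS",
    "make_classifier",
    "kfold_evaluate",
    "compute_metrics",
    "margin_of_error",
]


def _mlp(sizes):
    return lambda seed: MLPClassifier(
        hidden_layer_sizes=sizes, max_iter=800, random_state=seed
    )


#: name -> factory(seed) -> unfitted estimator. Widths 10/25/100 follow the
#: narrow/medium/wide presets; exact MATLAB parity is not promised.
CLASSIFIERS = {
    "fknn": lambda seed: KNeighborsClassifier(n_neighbors=1),
    "lsvm": lambda seed: SVC(kernel="linear", random_state=seed),
    "qsvm": lambda seed: SVC(kernel="poly", degree=2, coef0=1.0, random_state=seed),
    "csvm": lambda seed: SVC(kernel="poly", degree=3, coef0=1.0, random_state=seed),
    "mgsvm": lambda seed: SVC(kernel="rbf", random_state=seed),
    "nnn": _mlp((10,)),
    "mnn": _mlp((25,)),
    "wnn": _mlp((100,)),
    "bnn": _mlp((10, 10)),
    "tnn": _mlp((10, 10, 10)),
}


def make_classifier(name: str, seed: int = 0):
    try:
        return CLASSIFIERS[name](seed)
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; choose from {sorted(CLASSIFIERS)}"
        ) from None


@dataclass
class ConfusionMatrix:
    """C×C count grid, rows = true class, columns = predicted class."""

    matrix: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        self.classes = np.asarray(self.classes)
        c = len(self.classes)
        if self.matrix.shape != (c, c):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {c} classes"
            )
        if (self.matrix < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class MetricsReport:
    """The printed metric suite, all in percent except FPR (fraction)."""

    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    fpr: float
    kappa: float
    mcc: float
    per_class_correct: np.ndarray
    time_s: float | None = None
    warnings: list = field(default_factory=list)


def kfold_evaluate(
    X: FeatureMatrix, classifier: str = "fknn", k: int = 10, seed: int = 0
) -> tuple[ConfusionMatrix, float]:
    """Stratified k-fold CV; out-of-fold predictions pooled into one matrix.

    Returns ``(confusion_matrix, wall_time_seconds)``. The fold assignment
    is seeded, so the matrix is reproducible; the wall time is not.
    """
    classes, codes = np.unique(X.labels, return_inverse=True)
    counts = np.bincount(codes)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cm = np.zeros((classes.size, classes.size), dtype=np.int64)
    t0 = time.perf_counter()
    for train, test in skf.split(X.values, codes):
        clf = make_classifier(classifier, seed)
        clf.fit(X.values[train], codes[train])
        pred = clf.predict(X.values[test])
        np.add.at(cm, (codes[test], pred.astype(np.int64)), 1)
    elapsed = time.perf_counter() - t0
    return ConfusionMatrix(matrix=cm, classes=classes), elapsed


def compute_metrics(cm: ConfusionMatrix, time_s: float | None = None) -> MetricsReport:
    """Recompute the full metric suite from a confusion matrix.

    Per-class precision/sensitivity/F1/FPR are macro-averaged; classes with
    a zero denominator contribute 0 and raise a warning flag. Kappa and the
    multi-class MCC use their confusion-matrix forms.
    """
    M = cm.matrix.astype(np.float64)
    total = M.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    warnings: list[str] = []
    tp = np.diag(M)
    row = M.sum(axis=1)  # true counts
    col = M.sum(axis=0)  # predicted counts
    fn = row - tp
    fp = col - tp
    tn = total - tp - fn - fp

    def safe_div(num, den, what):
        out = np.zeros_like(num, dtype=np.float64)
        bad = den == 0
        if bad.any():
            warnings.append(f"zero denominator in per-class {what}; reported as 0")
        np.divide(num, den, out=out, where=~bad)
        return out

    precision = safe_div(tp, tp + fp, "precision")
    sensitivity = safe_div(tp, tp + fn, "sensitivity")
    f1 = safe_div(2 * precision * sensitivity, precision + sensitivity, "F1")
    fpr = safe_div(fp, fp + tn, "FPR")
    per_class_correct = safe_div(tp, row, "correct rate")

    accuracy = tp.sum() / total
    po = accuracy
    pe = float((row * col).sum()) / total**2
    if pe >= 1.0:
        kappa = 0.0
        warnings.append("degenerate chance agreement (pe = 1); kappa reported as 0")
    else:
        kappa = (po - pe) / (1.0 - pe)

    num = tp.sum() * total - float((row * col).sum())
    den = np.sqrt(total**2 - float((col * col).sum())) * np.sqrt(
        total**2 - float((row * row).sum())
    )
    if den == 0:
        mcc = 0.0
        warnings.append("degenerate marginals; MCC reported as 0")
    else:
        mcc = num / den

    return MetricsReport(
        accuracy=100.0 * accuracy,
        precision=100.0 * float(precision.mean()),
        sensitivity=100.0 * float(sensitivity.mean()),
        f1=100.0 * float(f1.mean()),
        fpr=float(fpr.mean()),
        kappa=100.0 * kappa,
        mcc=100.0 * mcc,
        per_class_correct=100.0 * per_class_correct,
        time_s=time_s,
        warnings=warnings,
    )


def margin_of_error(
    values: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float]:
    """Normal-approximation margin of error of a set of metric values.

    Returns ``(center, half_width, percent)`` with center the sample mean
    and half-width z * s / sqrt(n) (s = sample standard deviation, ddof 1).
    z is 1.0 at 68.3% confidence and 1.960 at 95%; other levels map through
    the normal quantile.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values for a margin of error")
    z_table = {0.683: 1.0, 0.95: 1.960}
    z = z_table.get(round(confidence, 3))
    if z is None:
        if not 0.0 < confidence < 1.0:
            raise ValueError(f"confidence must be in (0, 1), got {confidence}")
        z = float(norm.ppf((1.0 + confidence) / 2.0))
    center = float(values.mean())
    half = float(z * values.std(ddof=1) / np.sqrt(values.size))
    if half == 0.0:
        percent = 0.0
    elif center == 0.0:
        raise ValueError("percent margin undefined for zero-mean values")
    else:
        percent = 100.0 * half / abs(center)
    return center, half, percent
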