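"""Wrapper fitness: decode a learner, cross-validate a kernel SVM, score it.

The fitness of a learner is the mean held-out accuracy of a soft-margin SVM
over seeded stratified K folds, trained on the decoded feature subset with
the decoded penalty C and RBF width sigma (``gamma = 1/(2*sigma**2)``).
Standardization is fit on the training part of each fold only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from seqtlboga.qpop import BinaryLearner

__all__ = [
    "Dataset",
    "FitnessResult",
    "MetricSet",
    "decode",
    "evaluate_fitness",
    "compute_metrics",
]


@dataclass
class Dataset:
    """Tabular binary-classification data (label 1 = positive/malignant)."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must match the number of samples")
        if np.isnan(self.features).any():
            raise ValueError("features must not contain missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        # single-class data is loadable (e.g. one-row files) but rejected
        # at evaluation time, where both classes are genuinely required
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class FitnessResult:
    """Cross-validated score of one learner."""

    fitness: float
    fold_accuracies: np.ndarray
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN) summed over folds
    n_selected: int


@dataclass(frozen=True)
class MetricSet:
    """Confusion-derived metrics; undefined ratios are ``nan`` and flagged."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    auc_balanced: float
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    undefined: tuple[str, ...] = ()


def decode(binary: BinaryLearner, dataset: Dataset) -> tuple[np.ndarray, float, float]:
    """Column subset where the mask is 1, plus the (C, sigma) tail."""
    if binary.n_features != dataset.n_features:
        raise ValueError("mask length must equal the dataset feature count")
    cols = np.flatnonzero(binary.mask)
    return dataset.features[:, cols], binary.c_value, binary.sigma_value


def _sigma_to_gamma(sigma: float) -> float:
    # k(x, y) = exp(-||x-y||^2 / (2 sigma^2))
    return 1.0 / (2.0 * sigma * sigma)


def evaluate_fitness(
    learner: BinaryLearner,
    dataset: Dataset,
    k_folds: int = 10,
    kernel: str = "rbf",
    seed: int = 0,
) -> FitnessResult:
    """Mean fold accuracy of the decoded SVM under stratified K-fold CV.

    Deterministic given ``(learner, dataset, k_folds, kernel, seed)``.
    Degenerate single-class training folds are skipped with a warning and
    K is effectively reduced.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if kernel not in ("rbf", "poly", "linear"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    if learner.c_value <= 0 or learner.sigma_value <= 0:
        raise ValueError("C and sigma must be positive")
    counts = np.bincount(dataset.labels, minlength=2)
    if counts.min() < k_folds:
        raise ValueError("each class needs at least k_folds members")

    X, c_value, sigma = decode(learner, dataset)
    y = dataset.labels
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    tp = fp = tn = fn = 0
    for train_idx, test_idx in skf.split(X, y):
        y_train = y[train_idx]
        if len(set(y_train.tolist())) < 2:
            warnings.warn("single-class training fold skipped", stacklevel=2)
            continue
        scaler = StandardScaler().fit(X[train_idx])
        X_train = scaler.transform(X[train_idx])
        X_test = scaler.transform(X[test_idx])
        if kernel == "rbf":
            clf = SVC(C=c_value, kernel="rbf", gamma=_sigma_to_gamma(sigma))
        elif kernel == "poly":
            clf = SVC(C=c_value, kernel="poly", gamma=_sigma_to_gamma(sigma), degree=3)
        else:
            clf = SVC(C=c_value, kernel="linear")
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
        y_test = y[test_idx]
        fold_acc.append(float(np.mean(pred == y_test)))
        tp += int(np.sum((pred == 1) & (y_test == 1)))
        fp += int(np.sum((pred == 1) & (y_test == 0)))
        tn += int(np.sum((pred == 0) & (y_test == 0)))
        fn += int(np.sum((pred == 0) & (y_test == 1)))

    acc = np.asarray(fold_acc, dtype=float)
    return FitnessResult(
        fitness=float(acc.mean()),
        fold_accuracies=acc,
        confusion=(tp, fp, tn, fn),
        n_selected=learner.n_selected,
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def compute_metrics(confusion: tuple[int, int, int, int]) -> MetricSet:
    """Full metric suite from summed (TP, FP, TN, FN) counts.

    ``auc_balanced`` is the mean of sensitivity and specificity.  Zero
    denominators yield ``nan`` with the metric name recorded in
    ``undefined``.
    """
    tp, fp, tn, fn = confusion
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion counts must not all be zero")
    undefined: list[str] = []
    accuracy = (tp + tn) / total
    sensitivity = _ratio(tp, tp + fn, "sensitivity", undefined)
    specificity = _ratio(tn, fp + tn, "specificity", undefined)
    precision = _ratio(tp, tp + fp, "precision", undefined)
    if math.isnan(sensitivity) or math.isnan(precision) or (precision + sensitivity) == 0:
        undefined.append("f_score")
        f_score = math.nan
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    if math.isnan(sensitivity) or math.isnan(specificity):
        undefined.append("auc_balanced")
        auc = math.nan
    else:
        auc = (sensitivity + specificity) / 2.0
    # FPR uses the standard FP/(FP+TN) so that specificity + FPR = 1.
    fpr = _ratio(fp, fp + tn, "fpr", undefined)
    fnr = _ratio(fn, tp + fn, "fnr", undefined)
    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f_score=f_score,
        auc_balanced=auc,
        tpr=sensitivity,
        tnr=specificity,
        fpr=fpr,
        fnr=fnr,
        undefined=tuple(dict.fromkeys(undefined)),
    )
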