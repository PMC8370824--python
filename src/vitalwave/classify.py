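"""SVM / KNN respiratory-pattern classification with CV and agreement metrics.

Features are z-scored with training-set statistics inside a pipeline.
Defaults: RBF-kernel SVM (C = 1, gamma = 'scale', one-vs-one multiclass)
and KNN with k = 5 on Euclidean distance.  Evaluation reports carry the
confusion matrix (rows = true class, columns = predicted), the accuracy
(trace over total) and Cohen's kappa, the chance-corrected agreement
kappa = (p_o - p_e) / (1 - p_e) with p_e the product-of-marginals
expected agreement.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES

N_CLASSES = 5


@dataclass
class LabeledDataset:
    """Feature matrix (n x 8) with integer class labels 1-5."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"features must be n x {len(FEATURE_NAMES)}")
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features must have equal length")
        if np.any(np.isnan(self.features)):
            raise ValueError("features contain missing values")
        if not set(np.unique(self.labels)) <= set(range(1, N_CLASSES + 1)):
            raise ValueError(f"labels must lie in 1..{N_CLASSES}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.features[idx], self.labels[idx])


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, cols = predicted), accuracy, kappa."""

    confusion: np.ndarray
    accuracy: float
    kappa: float
    per_fold: list = field(default_factory=list)

    @property
    def mean_fold_accuracy(self) -> float:
        if not self.per_fold:
            raise ValueError("no per-fold accuracies recorded")
        return float(np.mean(self.per_fold))


def make_model(model: str = "svm", params: dict | None = None, seed: int = 0) -> Pipeline:
    """Standardizer + classifier pipeline for ``svm`` or ``knn``."""
    params = dict(params or {})
    if model == "svm":
        clf = SVC(
            kernel=params.pop("kernel", "rbf"),
            C=params.pop("C", 1.0),
            gamma=params.pop("gamma", "scale"),
            random_state=seed,
            **params,
        )
    elif model == "knn":
        clf = KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 5), **params)
    else:
        raise ValueError("model must be 'svm' or 'knn'")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_predict(
    train: LabeledDataset,
    test: LabeledDataset,
    model: str = "svm",
    params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fit on the training set and predict test labels (deterministic given seed)."""
    if len(train) == 0:
        raise ValueError("empty training set")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain at least two classes")
    if test.features.shape[1] != train.features.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    pipe = make_model(model, params, seed)
    pipe.fit(train.features, train.labels)
    return pipe.predict(test.features)


def confusion_and_kappa(
    y_true, y_pred, n_classes: int = N_CLASSES, labels=None
) -> EvalReport:
    """Confusion counts, accuracy = trace/total, and Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e), p_e = sum_c (row_c / N)(col_c / N).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    labels = list(labels) if labels is not None else list(range(1, n_classes + 1))
    index = {lab: i for i, lab in enumerate(labels)}
    conf = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    total = conf.sum()
    p_o = np.trace(conf) / total
    p_e = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0)) / total**2)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return EvalReport(confusion=conf, accuracy=float(p_o), kappa=float(kappa))


def kfold_cv(
    data: LabeledDataset,
    k: int = 10,
    model: str = "svm",
    params: dict | None = None,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation; folds deterministic given seed.

    Returns the aggregate confusion matrix over all test folds, its
    accuracy and kappa, plus the per-fold accuracy list.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(data.class_counts.values()) < k:
        raise ValueError("every class needs at least k samples for k folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    labels = sorted(np.unique(data.labels).tolist())
    conf = np.zeros((len(labels), len(labels)), dtype=int)
    per_fold = []
    for train_idx, test_idx in skf.split(data.features, data.labels):
        pred = train_predict(data.subset(train_idx), data.subset(test_idx), model, params, seed)
        fold = confusion_and_kappa(data.labels[test_idx], pred, labels=labels)
        conf += fold.confusion
        per_fold.append(fold.accuracy)
    agg = confusion_and_kappa_from_matrix(conf)
    agg.per_fold = per_fold
    return agg


def confusion_and_kappa_from_matrix(conf: np.ndarray) -> EvalReport:
    """EvalReport from an existing confusion matrix (rows = true)."""
    conf = np.asarray(conf, dtype=int)
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(conf) / total
    p_e = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0)) / total**2)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return EvalReport(confusion=conf, accuracy=float(p_o), kappa=float(kappa))
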