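"""The 12-learner grid (6 SVM + 6 KNN) and one-vs-one multiclass coding.

SVM kernels: linear, quadratic, cubic (polynomial, unit coefficient, box
constraint 1) and Gaussian at kernel scales 4*sqrt(N) (coarse), sqrt(N)
(medium), sqrt(N)/4 (fine), where N is the post-selection feature count;
the Gaussian kernel is exp(-||x - y||^2 / scale^2).

KNN variants: Euclidean K = 1 / 10 / 100 (coarse / medium / fine), cosine
K = 10, cubic (Minkowski order 3) K = 10, and squared-inverse-distance
weighted Euclidean K = 10. K is capped at the training-set size.

The full experiment census is 12 models x {raw, clean} x {5 selections}
x {demographics, none} x {2-class, 3-class} = 480 configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import schema_hash

SVM_KERNELS = ("linear", "quadratic", "cubic", "gaussian-coarse", "gaussian-medium", "gaussian-fine")
KNN_VARIANTS = ("coarse", "medium", "fine", "cosine", "cubic", "weighted")

GAUSSIAN_SCALE_FACTORS = {"gaussian-coarse": 4.0, "gaussian-medium": 1.0, "gaussian-fine": 0.25}
KNN_K = {"coarse": 1, "medium": 10, "fine": 100, "cosine": 10, "cubic": 10, "weighted": 10}


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the 12 learner configurations."""

    name: str
    family: str  # "SVM" | "KNN"

    def __post_init__(self) -> None:
        if self.family == "SVM" and self.name not in SVM_KERNELS:
            raise ValueError(f"unknown SVM kernel {self.name!r}")
        if self.family == "KNN" and self.name not in KNN_VARIANTS:
            raise ValueError(f"unknown KNN variant {self.name!r}")
        if self.family not in ("SVM", "KNN"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def label(self) -> str:
        return f"{self.family}-{self.name}"


def enumerate_model_grid() -> list[ClassifierSpec]:
    """The 12 learner specs, SVM first, in printed order."""
    return [ClassifierSpec(name=k, family="SVM") for k in SVM_KERNELS] + [
        ClassifierSpec(name=k, family="KNN") for k in KNN_VARIANTS
    ]


def gaussian_kernel_scale(variant: str, n_features: int) -> float:
    """Kernel scale 4*sqrt(N) / sqrt(N) / sqrt(N)/4 for coarse/medium/fine."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return GAUSSIAN_SCALE_FACTORS[variant] * float(np.sqrt(n_features))


def _squared_inverse(distances: np.ndarray) -> np.ndarray:
    # exact neighbors (d == 0) get all the weight, mirroring standard practice
    with np.errstate(divide="ignore"):
        w = 1.0 / np.asarray(distances) ** 2
    if np.isinf(w).any():
        w = np.where(np.isinf(w), 1.0, 0.0)
    return w


def build_estimator(spec: ClassifierSpec, n_features: int, n_train: int):
    """Instantiate the scikit-learn estimator for a spec.

    The Gaussian kernel scale is recomputed from the post-selection feature
    count; K is capped at the training-set size (with a warning).
    """
    if spec.family == "SVM":
        if spec.name == "linear":
            return SVC(kernel="linear", C=1.0)
        if spec.name == "quadratic":
            return SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0, C=1.0)
        if spec.name == "cubic":
            return SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=1.0)
        scale = gaussian_kernel_scale(spec.name, n_features)
        return SVC(kernel="rbf", gamma=1.0 / scale**2, C=1.0)
    k = KNN_K[spec.name]
    if k > n_train:
        warnings.warn(
            f"K={k} exceeds training size {n_train}; capping", stacklevel=2
        )
        k = n_train
    if spec.name == "cosine":
        return KNeighborsClassifier(n_neighbors=k, metric="cosine")
    if spec.name == "cubic":
        return KNeighborsClassifier(n_neighbors=k, metric="minkowski", p=3)
    if spec.name == "weighted":
        return KNeighborsClassifier(n_neighbors=k, weights=_squared_inverse)
    return KNeighborsClassifier(n_neighbors=k)


@dataclass
class TrainedModel:
    """A fitted learner bound to its training feature schema."""

    spec: ClassifierSpec
    estimators: list  # 1 for binary, C(g, 2) for one-vs-one multiclass
    pairs: list[tuple] | None  # class pairs for OVO; None for binary
    classes: np.ndarray
    schema: str

    def _check(self, table: pd.DataFrame) -> np.ndarray:
        if schema_hash(table.columns) != self.schema:
            raise ValueError("feature schema mismatch between training and prediction")
        return table.to_numpy(dtype=float)


def train_classifier(
    spec: ClassifierSpec, table: pd.DataFrame, labels: pd.Series | np.ndarray
) -> TrainedModel:
    """Fit one binary learner."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary training needs 2 classes, got {len(classes)}")
    X = table.to_numpy(dtype=float)
    est = build_estimator(spec, X.shape[1], X.shape[0])
    est.fit(X, y)
    return TrainedModel(
        spec=spec, estimators=[est], pairs=None, classes=classes,
        schema=schema_hash(table.columns),
    )


def train_multiclass_ovo(
    spec: ClassifierSpec, table: pd.DataFrame, labels: pd.Series | np.ndarray
) -> TrainedModel:
    """Error-correcting output codes with one-vs-one coding: one binary
    learner per class pair; prediction decodes by vote count (minimal code
    distance), ties broken toward the lowest class index."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 3:
        raise ValueError("one-vs-one coding needs >= 3 classes")
    X = table.to_numpy(dtype=float)
    estimators, pairs = [], []
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        est = build_estimator(spec, X.shape[1], int(mask.sum()))
        est.fit(X[mask], y[mask])
        estimators.append(est)
        pairs.append((a, b))
    return TrainedModel(
        spec=spec, estimators=estimators, pairs=pairs, classes=classes,
        schema=schema_hash(table.columns),
    )


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """One label per row; deterministic; schema-checked."""
    X = model._check(table)
    if X.shape[0] == 0:
        return np.array([], dtype=model.classes.dtype)
    if model.pairs is None:
        return model.estimators[0].predict(X)
    class_idx = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((X.shape[0], len(model.classes)), dtype=int)
    for est in model.estimators:
        pred = est.predict(X)
        for c, i in class_idx.items():
            votes[pred == c, i] += 1
    # argmax returns the first maximum -> lowest class index wins ties
    return model.classes[np.argmax(votes, axis=1)]


def fit_predictor(
    spec: ClassifierSpec, table: pd.DataFrame, labels: pd.Series | np.ndarray
) -> TrainedModel:
    """Dispatch binary / one-vs-one training on the number of classes."""
    n_classes = len(np.unique(np.asarray(labels)))
    if n_classes == 2:
        return train_classifier(spec, table, labels)
    return train_multiclass_ovo(spec, table, labels)
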