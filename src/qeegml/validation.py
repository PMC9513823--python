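"""Validation protocol: repeated 10-fold cross-validation, random-label
permutation null, independent validation, ZeroR and normal-vs-abnormal
theoretical benchmarks, two-sample K-S model comparison, and the
confusion-matrix metric suite.

The per-iteration CV statistic is the cumulative (fold-pooled) accuracy:
correct predictions summed over all folds divided by n. Folds are
unstratified uniform random partitions. By default feature standardization
and selection happen upstream on the full training table (the reference
protocol, which is optimistic); passing ``fold_transform`` re-fits a
transform inside every fold instead (nested mode) so the bias can be
measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .classifiers import ClassifierSpec, TrainedModel, build_estimator, predict

#: a fold_transform takes (train_table, train_labels) and returns a function
#: mapping any table into the fitted feature space
FoldTransform = Callable[[pd.DataFrame, np.ndarray], Callable[[pd.DataFrame], pd.DataFrame]]


@dataclass
class AccuracyDistribution:
    """Per-iteration pooled-fold accuracies from repeated k-fold CV."""

    samples: np.ndarray
    k: int
    seed: int
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any((self.samples < 0) | (self.samples > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def n_iterations(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    def summary(self) -> dict:
        return {
            "label": self.label,
            "n_iterations": self.n_iterations,
            "k": self.k,
            "seed": self.seed,
            "mean": self.mean,
            "sd": float(self.samples.std(ddof=1)) if self.n_iterations > 1 else 0.0,
            "median": float(np.median(self.samples)),
        }


@dataclass
class MetricsReport:
    """Confusion-matrix metrics with per-class and aggregate variants."""

    accuracy: float
    confusion: pd.DataFrame  # rows = truth, columns = predicted
    per_class: pd.DataFrame  # sensitivity / specificity / precision / f1
    macro: dict[str, float]
    weighted: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.to_dict(),
            "per_class": self.per_class.to_dict(),
            "macro": self.macro,
            "weighted": self.weighted,
        }


def _one_cv_accuracy(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    y: np.ndarray,
    k: int,
    rs: int,
    fold_transform: FoldTransform | None,
) -> float:
    from .classifiers import fit_predictor

    correct = 0
    kf = KFold(n_splits=k, shuffle=True, random_state=rs)
    for tr, te in kf.split(table):
        tr_tab, te_tab = table.iloc[tr], table.iloc[te]
        if fold_transform is not None:
            mapper = fold_transform(tr_tab, y[tr])
            tr_tab, te_tab = mapper(tr_tab), mapper(te_tab)
        if len(np.unique(y[tr])) < 2:
            # degenerate fold: predict the single training class
            correct += int(np.sum(y[te] == y[tr][0]))
            continue
        model = fit_predictor(spec, tr_tab, y[tr])
        correct += int(np.sum(predict(model, te_tab) == y[te]))
    return correct / len(y)


def repeated_kfold_cv(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 10,
    iters: int = 1000,
    seed: int = 0,
    fold_transform: FoldTransform | None = None,
) -> AccuracyDistribution:
    """Repeat k-fold CV over ``iters`` fresh random partitions.

    Deterministic given ``seed``; per-iteration partition seeds derive from
    ``seed`` + iteration index.
    """
    y = np.asarray(labels)
    if len(y) < k:
        raise ValueError(f"n={len(y)} smaller than k={k}")
    samples = np.array(
        [
            _one_cv_accuracy(spec, table, y, k, (seed + it) % 2**31, fold_transform)
            for it in range(iters)
        ]
    )
    return AccuracyDistribution(samples=samples, k=k, seed=seed, label="true-label CV")


def random_label_null(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 10,
    iters: int = 1000,
    seed: int = 0,
    fold_transform: FoldTransform | None = None,
) -> AccuracyDistribution:
    """Permutation null: labels shuffled uniformly per iteration, then the
    identical CV procedure applied."""
    y = np.asarray(labels)
    if len(y) < k:
        raise ValueError(f"n={len(y)} smaller than k={k}")
    rng = np.random.default_rng(seed)
    samples = []
    for it in range(iters):
        y_perm = rng.permutation(y)
        samples.append(
            _one_cv_accuracy(spec, table, y_perm, k, (seed + it) % 2**31, fold_transform)
        )
    return AccuracyDistribution(
        samples=np.array(samples), k=k, seed=seed, label="random-label null"
    )


def compare_to_null(
    true_dist: AccuracyDistribution | np.ndarray,
    null_dist: AccuracyDistribution | np.ndarray,
    alpha: float = 1e-10,
) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison of accuracy distributions.

    ``significant`` requires both p < alpha and a higher true-label mean.
    """
    t = true_dist.samples if isinstance(true_dist, AccuracyDistribution) else np.asarray(true_dist)
    n = null_dist.samples if isinstance(null_dist, AccuracyDistribution) else np.asarray(null_dist)
    if len(t) == 0 or len(n) == 0:
        raise ValueError("distributions must be non-empty")
    if np.array_equal(t, n):
        ks_p, ks_stat = 1.0, 0.0
    else:
        res = stats.ks_2samp(t, n)
        ks_p, ks_stat = float(res.pvalue), float(res.statistic)
    better = bool(t.mean() > n.mean())
    return {
        "ks_statistic": ks_stat,
        "p_value": ks_p,
        "alpha": alpha,
        "mean_true": float(t.mean()),
        "mean_null": float(n.mean()),
        "significant": bool(ks_p < alpha and better),
    }


def classification_metrics(
    truth: Sequence, predicted: Sequence, classes: Sequence | None = None
) -> MetricsReport:
    """Accuracy, confusion matrix, and per-class one-vs-rest sensitivity /
    specificity / precision / F1 with macro and truth-count-weighted
    aggregates."""
    y_t = np.asarray(truth)
    y_p = np.asarray(predicted)
    if len(y_t) != len(y_p):
        raise ValueError("truth and prediction lengths differ")
    if classes is None:
        classes = np.unique(y_t)
    classes = np.asarray(classes)
    unknown = set(np.unique(y_p)) - set(classes)
    if unknown:
        raise ValueError(f"predicted labels outside class set: {unknown}")
    n = len(y_t)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_t, y_p):
        conf[idx[t], idx[p]] += 1
    accuracy = float(np.trace(conf) / n) if n else 0.0
    rows = {}
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        rows[c] = {"sensitivity": sens, "specificity": spec, "precision": prec, "f1": f1}
    per_class = pd.DataFrame(rows).T
    weights = conf.sum(axis=1) / n if n else np.zeros(len(classes))
    macro = {m: float(per_class[m].mean()) for m in per_class.columns}
    weighted = {m: float((per_class[m].to_numpy() * weights).sum()) for m in per_class.columns}
    return MetricsReport(
        accuracy=accuracy,
        confusion=pd.DataFrame(conf, index=classes, columns=classes),
        per_class=per_class,
        macro=macro,
        weighted=weighted,
    )


def zeror(counts: Sequence[float]) -> float:
    """Majority-class fraction: the Zero Rule benchmark accuracy."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    return float(c.max() / total)


def abnormal_detector_bound(counts: Sequence[float]) -> float:
    """Accuracy ceiling of a three-class model that only separates normal
    from abnormal: P(normal) * 1 + P(TBI)^2 + P(stroke)^2 with class
    probabilities taken as the observed fractions (the two abnormal classes
    are guessed at random in proportion to their prevalence)."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,):
        raise ValueError("exactly three class counts (normal, TBI, stroke) required")
    if np.any(c < 0) or c.sum() <= 0:
        raise ValueError("counts must be >= 0 with a positive total")
    p = c / c.sum()
    return float(p[0] + p[1] ** 2 + p[2] ** 2)


def independent_validate(
    model: TrainedModel, iv_table: pd.DataFrame, iv_labels: pd.Series | np.ndarray
) -> tuple[MetricsReport, bool]:
    """Score a trained model on withheld subjects.

    Success requires accuracy strictly above the ZeroR benchmark of the IV
    label counts (a majority-class predictor is not a success).
    """
    y = np.asarray(iv_labels)
    pred = predict(model, iv_table)
    report = classification_metrics(y, pred, classes=model.classes)
    _, counts = np.unique(y, return_counts=True)
    success = bool(report.accuracy > zeror(counts))
    return report, success
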