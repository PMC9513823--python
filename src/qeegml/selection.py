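"""Feature selection: the five dimensionality-reduction routes.

* ``stat_select`` — per-feature hypothesis tests (rank-sum for two classes,
  one-way ANOVA with post-hoc Tukey diagnostics for three) gated by
  Benjamini-Hochberg FDR at q = 0.05; categorical sex enters through a
  chi-square contingency test.
* ``lda_select`` — regularized linear discriminant (gamma: covariance
  shrinkage toward its diagonal; delta: coefficient soft-thresholding)
  tuned over a 50 x 50 grid by cross-validated misclassification, then
  coefficient-magnitude thresholding at mean(|coef|) + 1 SD.
* ``sequential_select`` — greedy forward / backward selection by mean
  10-fold-CV misclassification of a linear discriminant over Monte-Carlo
  repartitions; backward starts from the LDA survivors.
* ``pca_select`` — minimal leading principal components reaching >= 95%
  cumulative explained variance (categorical sex bypasses the rotation).
* ``standardize_features`` — train-statistics z-scoring applied to held-out
  tables (no leakage), with the categorical sex column exempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold

CATEGORICAL_FEATURES = ("demo:sex",)


@dataclass
class SelectionResult:
    """Outcome of one selection method."""

    method: str
    selected: list[str]
    #: diagnostics: p-values, criterion traces, chosen hyper-parameters ...
    trace: dict = field(default_factory=dict)
    #: PCA only: (n_components, n_features) orthonormal loadings
    loadings: pd.DataFrame | None = None
    #: PCA only: train-table feature means removed before rotation
    center: pd.Series | None = None

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        """Project a feature table onto the selected space."""
        if self.loadings is None:
            return table[self.selected]
        num = self.loadings.columns
        scores = (table[num] - self.center[num]) @ self.loadings.T
        scores.columns = [f"PC{i + 1}" for i in range(scores.shape[1])]
        passthrough = [c for c in CATEGORICAL_FEATURES if c in table.columns]
        if passthrough:
            scores = pd.concat([scores, table[passthrough]], axis=1)
        return scores

    def to_dict(self) -> dict:
        d = {"method": self.method, "selected": list(self.selected)}
        d["trace"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.trace.items()
        }
        return d


# --- standardization ----------------------------------------------------------


def standardize_features(
    train_table: pd.DataFrame,
    *other_tables: pd.DataFrame,
    exempt: Sequence[str] = CATEGORICAL_FEATURES,
) -> tuple[pd.DataFrame, ...]:
    """Z-score with training-set statistics; held-out tables reuse them.

    Zero-variance training features get SD 1 (their standardized values are
    0) and are reported in ``.attrs['constant_features']``.
    """
    cols = [c for c in train_table.columns if c not in exempt]
    mean = train_table[cols].mean()
    sd = train_table[cols].std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    sd = sd.replace(0.0, 1.0).fillna(1.0)
    outs = []
    for tab in (train_table, *other_tables):
        out = tab.copy()
        out[cols] = (tab[cols] - mean) / sd
        out.attrs["constant_features"] = constant
        outs.append(out)
    return tuple(outs)


# --- BH / statistics ------------------------------------------------------------


def bh_select(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: indices of the k smallest p-values where
    k is the largest rank with ``p_(k) <= q * k / m``; empty if none."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    ranks = np.arange(1, m + 1)
    passing = np.flatnonzero(p[order] <= q * ranks / m)
    if passing.size == 0:
        return np.array([], dtype=int)
    k = passing[-1] + 1
    return np.sort(order[:k])


def stat_select(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    q: float = 0.05,
    normality_alpha: float = 0.05,
) -> SelectionResult:
    """Univariate screening with BH FDR control.

    Numeric features: Wilcoxon rank-sum (two classes) or one-way ANOVA with
    post-hoc Tukey recorded as diagnostics (three classes). A one-sample
    Kolmogorov-Smirnov normality check per feature is recorded but does not
    gate the branch. Categorical sex: chi-square contingency test. Constant
    features get p = 1 and are never selected.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    groups_idx = [labels == c for c in classes]
    pvals, names, normal_flags = [], [], {}
    tukey: dict[str, dict] = {}
    branch = "ranksum" if len(classes) == 2 else "anova"
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        names.append(col)
        if col in CATEGORICAL_FEATURES:
            cats = np.unique(x)
            counts = np.array([[np.sum((x == v) & g) for v in cats] for g in groups_idx])
            counts = counts[:, counts.sum(axis=0) > 0]
            if counts.shape[1] < 2:
                pvals.append(1.0)
            else:
                pvals.append(float(stats.chi2_contingency(counts).pvalue))
            continue
        if np.ptp(x) == 0:
            pvals.append(1.0)
            normal_flags[col] = False
            continue
        z = (x - x.mean()) / x.std()
        normal_flags[col] = bool(stats.kstest(z, "norm").pvalue >= normality_alpha)
        samples = [x[g] for g in groups_idx]
        if len(classes) == 2:
            pvals.append(float(stats.ranksums(samples[0], samples[1]).pvalue))
        else:
            pvals.append(float(stats.f_oneway(*samples).pvalue))
            res = stats.tukey_hsd(*samples)
            tukey[col] = {
                f"{classes[i]}|{classes[j]}": float(res.pvalue[i, j])
                for i, j in combinations(range(len(classes)), 2)
            }
    pvals_arr = np.asarray(pvals)
    idx = bh_select(pvals_arr, q=q)
    selected = [names[i] for i in idx]
    trace = {
        "branch": branch,
        "pvalues": dict(zip(names, pvals_arr.tolist())),
        "q": q,
        "n_tests": len(names),
        "normality": normal_flags,
        "frac_normal": float(np.mean(list(normal_flags.values()))) if normal_flags else 0.0,
    }
    if tukey:
        trace["tukey"] = tukey
    return SelectionResult(method="statistics", selected=selected, trace=trace)


# --- regularized LDA -------------------------------------------------------------


class RegularizedLDA:
    """Binary linear discriminant with toward-diagonal covariance shrinkage
    (``gamma``) and coefficient soft-thresholding (``delta``).

    The pooled within-class covariance is shrunk as
    ``S(gamma) = (1 - gamma) S + gamma diag(S)`` and the discriminant
    direction solves ``S(gamma) w = mu_1 - mu_0``. For wide tables
    (features >> subjects) the solve uses the Woodbury identity on the
    low-rank centered data, so cost scales with subjects, not features.
    Coefficients with ``|w_j| < delta`` are zeroed before prediction.
    """

    def __init__(self, gamma: float = 0.5, delta: float = 0.0):
        if not 0 <= gamma <= 1:
            raise ValueError("gamma must be in [0, 1]")
        self.gamma = gamma
        self.delta = delta

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegularizedLDA":
        X = np.asarray(X, dtype=float)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("RegularizedLDA is binary")
        self.classes_ = classes
        n, p = X.shape
        masks = [y == c for c in classes]
        mus = [X[m].mean(axis=0) for m in masks]
        W = np.vstack([X[m] - mu for m, mu in zip(masks, mus)])  # centered rows
        nu = max(n - 2, 1)
        diag = (W**2).sum(axis=0) / nu
        eps = 1e-12 + 1e-8 * float(diag.mean())
        d_reg = self.gamma * diag + eps
        dmu = mus[1] - mus[0]
        g1 = 1.0 - self.gamma
        if g1 <= 0:
            w = dmu / d_reg
        else:
            # Woodbury: (D + c A^T A)^-1 v with A = W (n x p), c = g1/nu
            c = g1 / nu
            Dv = dmu / d_reg
            AD = W / d_reg  # n x p
            K = np.eye(n) / c + W @ AD.T
            w = Dv - AD.T @ np.linalg.solve(K, W @ Dv)
        self.raw_coef_ = w
        self.coef_ = np.where(np.abs(w) < self.delta, 0.0, w)
        self.intercept_ = (
            -0.5 * float(self.coef_ @ (mus[0] + mus[1]))
            + np.log(masks[1].sum() / masks[0].sum())
        )
        return self

    def set_delta(self, delta: float) -> "RegularizedLDA":
        """Re-threshold coefficients without refitting (grid-search helper)."""
        self.delta = delta
        self.coef_ = np.where(np.abs(self.raw_coef_) < delta, 0.0, self.raw_coef_)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


@dataclass
class LdaSelectionConfig:
    """Grid-search configuration for the LDA selector.

    ``n_steps`` grid points per axis (gamma linear on [0, 1]; delta
    log-spaced over ``delta_decades`` times the median |coefficient| scale),
    ``cv_folds``-fold CV misclassification as the criterion.
    """

    n_steps: int = 50
    gamma_range: tuple[float, float] = (0.0, 1.0)
    delta_decades: tuple[float, float] = (1e-4, 10.0)
    cv_folds: int = 5
    seed: int = 0


def _lda_grid_binary(
    X: np.ndarray, y: np.ndarray, config: LdaSelectionConfig
) -> tuple[float, float, np.ndarray, dict]:
    """Best (gamma, delta) by CV misclassification; returns the full-data
    delta-thresholded coefficients at the optimum."""
    rng_state = config.seed
    n = len(y)
    folds = KFold(n_splits=min(config.cv_folds, n), shuffle=True, random_state=rng_state)
    gammas = np.linspace(*config.gamma_range, config.n_steps)
    # delta grid scale from a mid-regularization full-data fit
    ref = RegularizedLDA(gamma=0.5).fit(X, y)
    scale = np.median(np.abs(ref.raw_coef_)) or 1.0
    deltas = scale * np.geomspace(*config.delta_decades, config.n_steps)
    err = np.zeros((len(gammas), len(deltas)))
    for tr, te in folds.split(X):
        Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
        for i, g in enumerate(gammas):
            model = RegularizedLDA(gamma=g).fit(Xtr, ytr)
            for j, d in enumerate(deltas):
                pred = model.set_delta(d).predict(Xte)
                err[i, j] += np.sum(pred != yte)
    err /= n
    i, j = np.unravel_index(np.argmin(err), err.shape)
    best_gamma, best_delta = float(gammas[i]), float(deltas[j])
    final = RegularizedLDA(gamma=best_gamma, delta=best_delta).fit(X, y)
    info = {
        "gamma": best_gamma,
        "delta": best_delta,
        "cv_error": float(err[i, j]),
        "grid_shape": list(err.shape),
    }
    return best_gamma, best_delta, final.coef_, info


def lda_select(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: LdaSelectionConfig | None = None,
) -> SelectionResult:
    """Select features by regularized-LDA coefficient magnitude.

    After grid search, features whose |coefficient| falls below
    mean(|coefficients|) + 1 SD are eliminated; features exactly at the
    threshold are kept. With three or more classes, one-vs-one discriminants
    are fitted and the survivor sets are unioned.
    """
    if config is None:
        config = LdaSelectionConfig()
    labels = np.asarray(labels)
    X = table.to_numpy(dtype=float)
    classes = np.unique(labels)
    survivors: set[str] = set()
    infos = []
    pair_list = (
        [(classes[0], classes[1])] if len(classes) == 2
        else list(combinations(classes, 2))
    )
    for a, b in pair_list:
        mask = (labels == a) | (labels == b)
        _, _, coef, info = _lda_grid_binary(X[mask], labels[mask], config)
        abs_c = np.abs(coef)
        threshold = abs_c.mean() + abs_c.std(ddof=0)
        keep = np.flatnonzero(abs_c >= threshold)
        survivors.update(table.columns[k] for k in keep)
        info["pair"] = f"{a}|{b}"
        info["threshold"] = float(threshold)
        info["n_kept"] = int(len(keep))
        infos.append(info)
    selected = [c for c in table.columns if c in survivors]  # canonical order
    return SelectionResult(
        method="lda", selected=selected, trace={"pairs": infos, "config": vars(config)}
    )


# --- sequential selection ---------------------------------------------------------


def _cv_misclassification(
    X: np.ndarray,
    y: np.ndarray,
    cols: list[int],
    cv_folds: int,
    mc_reps: int,
    seed: int,
) -> float:
    """Mean misclassification of a linear discriminant on the column subset,
    averaged over Monte-Carlo k-fold repartitions."""
    n = len(y)
    if not cols:
        # empty model predicts the training majority class
        _, counts = np.unique(y, return_counts=True)
        return 1.0 - counts.max() / n
    Xs = X[:, cols]
    errs = []
    for rep in range(mc_reps):
        kf = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=seed + rep)
        wrong = 0
        for tr, te in kf.split(Xs):
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            clf.fit(Xs[tr], y[tr])
            wrong += int(np.sum(clf.predict(Xs[te]) != y[te]))
        errs.append(wrong / n)
    return float(np.mean(errs))


def sequential_select(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    direction: str = "forward",
    start_set: Sequence[str] | None = None,
    cv_folds: int = 10,
    mc_reps: int = 50,
    seed: int = 0,
    max_moves: int | None = None,
) -> SelectionResult:
    """Greedy sequential feature selection by CV misclassification.

    Forward starts empty and adds the single best feature per step; backward
    starts from ``start_set`` (the LDA survivors in the reference protocol)
    and removes the single most dispensable feature per step. Iteration
    stops when no move strictly lowers the criterion. Ties break toward the
    lowest column index.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    X = table.to_numpy(dtype=float)
    cols = list(table.columns)
    if direction == "forward":
        if start_set:
            raise ValueError("forward selection starts from the empty set")
        current: list[int] = []
    elif direction == "backward":
        if not start_set:
            raise ValueError("backward selection needs a non-empty start_set")
        current = [cols.index(c) for c in start_set]
    else:
        raise ValueError("direction must be 'forward' or 'backward'")

    crit = _cv_misclassification(X, labels, current, cv_folds, mc_reps, seed)
    history = [(tuple(current), crit)]
    moves = 0
    while max_moves is None or moves < max_moves:
        candidates: list[int]
        if direction == "forward":
            candidates = [j for j in range(len(cols)) if j not in current]
            trial_sets = [current + [j] for j in candidates]
        else:
            candidates = list(current)
            trial_sets = [[k for k in current if k != j] for j in candidates]
        if not candidates:
            break
        scores = [
            _cv_misclassification(X, labels, t, cv_folds, mc_reps, seed)
            for t in trial_sets
        ]
        best = int(np.argmin(scores))  # argmin takes the first (lowest index) tie
        if scores[best] >= crit:
            break
        current = sorted(trial_sets[best])
        crit = scores[best]
        history.append((tuple(current), crit))
        moves += 1
    selected = [cols[j] for j in sorted(current)]
    return SelectionResult(
        method=f"{direction[0]}sfs",
        selected=selected,
        trace={
            "criterion": crit,
            "history": [(list(s), e) for s, e in history],
            "cv_folds": cv_folds,
            "mc_reps": mc_reps,
            "seed": seed,
        },
    )


# --- PCA ---------------------------------------------------------------------------


def pca_select(
    table: pd.DataFrame,
    var_threshold: float = 0.95,
) -> SelectionResult:
    """Minimal leading principal components with cumulative explained
    variance >= ``var_threshold``; categorical sex bypasses the rotation and
    is re-appended by :meth:`SelectionResult.apply`."""
    num_cols = [c for c in table.columns if c not in CATEGORICAL_FEATURES]
    X = table[num_cols].to_numpy(dtype=float)
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance table")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_threshold) + 1)
    k = min(k, len(cum))
    loadings = pd.DataFrame(pca.components_[:k], columns=num_cols)
    return SelectionResult(
        method="pca",
        selected=[f"PC{i + 1}" for i in range(k)],
        trace={
            "explained_variance_ratio": pca.explained_variance_ratio_[:k].tolist(),
            "cumulative": float(cum[k - 1]),
            "n_components": k,
        },
        loadings=loadings,
        center=table[num_cols].mean(),
    )
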