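"""Feature selection: BH step-up, statistical screening, regularized-LDA
coefficient thresholding, sequential selection, PCA, standardization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from qeegml.selection import (
    LdaSelectionConfig,
    RegularizedLDA,
    bh_select,
    lda_select,
    pca_select,
    sequential_select,
    standardize_features,
    stat_select,
)


def bh_bruteforce(p, q=0.05):
    """Oracle: scan every rank k for the BH inequality directly."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            best_k = k
    return np.sort(order[:best_k])


class TestBhSelect:
    def test_all_pass_when_largest_satisfies_inequality(self):
        # 0.04 <= 0.05 * 3/3 -> every rank significant
        np.testing.assert_array_equal(bh_select([0.01, 0.02, 0.04]), [0, 1, 2])

    def test_none_pass(self):
        assert bh_select([0.2, 0.5]).size == 0
        # 0.04 > 0.05 * 1/3: even the smallest p fails its rank inequality
        assert bh_select([0.04, 0.2, 0.9]).size == 0

    def test_empty_input(self):
        assert bh_select([]).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_select([0.5, 1.2])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
        st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_matches_bruteforce_scan(self, pvals, q):
        np.testing.assert_array_equal(bh_select(pvals, q), bh_bruteforce(pvals, q))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        rejected, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(bh_select(pvals), np.flatnonzero(rejected))


class TestStatSelect:
    def test_constant_feature_never_selected(self, rng):
        X = pd.DataFrame(
            {"const": np.ones(40), "noise": rng.standard_normal(40)}
        )
        y = np.array(["A"] * 20 + ["B"] * 20)
        res = stat_select(X, y)
        assert "const" not in res.selected
        assert res.trace["pvalues"]["const"] == 1.0

    def test_separated_feature_selected_with_fdr_control(self, rng):
        n = 50
        X = pd.DataFrame(
            rng.standard_normal((2 * n, 100)), columns=[f"f{i}" for i in range(100)]
        )
        y = np.array(["A"] * n + ["B"] * n)
        X.loc[y == "B", "f0"] += 5.0  # 5 SD separation
        res = stat_select(X, y)
        assert "f0" in res.selected
        false_hits = [c for c in res.selected if c != "f0"]
        assert len(false_hits) <= 10  # FDR 0.05 on 99 nulls

    def test_branch_dispatch(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        res2 = stat_select(X, np.array(["A"] * 15 + ["B"] * 15))
        assert res2.trace["branch"] == "ranksum"
        res3 = stat_select(X, np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10))
        assert res3.trace["branch"] == "anova"
        assert "tukey" in res3.trace  # post-hoc recorded as diagnostics

    def test_categorical_sex_contingency(self, rng):
        n = 40
        sex = np.array([0.0] * n + [1.0] * n)  # perfectly class-associated
        X = pd.DataFrame({"demo:sex": sex, "noise": rng.standard_normal(2 * n)})
        y = np.array(["A"] * n + ["B"] * n)
        res = stat_select(X, y)
        assert "demo:sex" in res.selected


class TestRegularizedLDA:
    def test_matches_sklearn_direction_full_rank(self, rng):
        X = rng.standard_normal((200, 8))
        y = (X[:, 0] + X[:, 1] + 0.5 * rng.standard_normal(200) > 0).astype(int)
        ours = RegularizedLDA(gamma=0.0).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        cos = np.dot(ours.coef_, ref.coef_[0]) / (
            np.linalg.norm(ours.coef_) * np.linalg.norm(ref.coef_[0])
        )
        assert cos == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_array_equal(ours.predict(X), ref.predict(X))

    def test_woodbury_equals_dense_solve_wide_table(self, rng):
        """p >> n path agrees with the explicit dense shrunk-covariance solve."""
        n, p, gamma = 30, 120, 0.3
        X = rng.standard_normal((n, p))
        y = np.array([0] * 15 + [1] * 15)
        X[y == 1, :3] += 1.0
        model = RegularizedLDA(gamma=gamma).fit(X, y)
        mus = [X[y == c].mean(axis=0) for c in (0, 1)]
        W = np.vstack([X[y == c] - mu for c, mu in zip((0, 1), mus)])
        S = W.T @ W / (n - 2)
        eps = 1e-12 + 1e-8 * float(np.diag(S).mean())
        S_reg = (1 - gamma) * S + gamma * np.diag(np.diag(S)) + eps * np.eye(p)
        w_dense = np.linalg.solve(S_reg, mus[1] - mus[0])
        np.testing.assert_allclose(model.raw_coef_, w_dense, rtol=1e-6, atol=1e-9)

    def test_singular_scatter_never_fatal(self, rng):
        X = rng.standard_normal((10, 50))  # p >> n: scatter singular
        y = np.array([0] * 5 + [1] * 5)
        for gamma in (0.0, 0.5, 1.0):
            RegularizedLDA(gamma=gamma).fit(X, y).predict(X)


class TestLdaSelect:
    def test_recovers_informative_features(self, rng):
        """5 informative of 100; selected overlap >= 4 in >= 90% of seeds."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(
                r.standard_normal((60, 100)), columns=[f"f{i}" for i in range(100)]
            )
            y = np.array(["A"] * 30 + ["B"] * 30)
            X.loc[y == "B", [f"f{i}" for i in range(5)]] += 3.0
            (Xs,) = standardize_features(X)
            res = lda_select(Xs, y, LdaSelectionConfig(n_steps=20, seed=seed))
            overlap = len(set(res.selected) & {f"f{i}" for i in range(5)})
            hits += overlap >= 4
        assert hits >= 9

    def test_duplicated_feature_boundary_kept(self, rng):
        """Exactly equal coefficients put every feature at the threshold
        (mean + 0 SD); at-threshold features are kept."""
        x = rng.standard_normal(40)
        y = np.array(["A"] * 20 + ["B"] * 20)
        x[y == "B"] += 2.0
        X = pd.DataFrame({"f0": x, "f1": x.copy()})
        res = lda_select(X, y, LdaSelectionConfig(n_steps=10, seed=0))
        assert set(res.selected) == {"f0", "f1"}

    def test_multiclass_unions_pairwise_survivors(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 12)), columns=[f"f{i}" for i in range(12)])
        y = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        X.loc[y == "B", "f0"] += 4.0
        X.loc[y == "C", "f1"] += 4.0
        res = lda_select(X, y, LdaSelectionConfig(n_steps=10, seed=0))
        assert len(res.trace["pairs"]) == 3
        assert {"f0", "f1"} <= set(res.selected)


class TestSequentialSelect:
    def test_forward_picks_separating_feature_first(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 10)), columns=[f"f{i}" for i in range(10)])
        y = np.array(["A"] * 20 + ["B"] * 20)
        X.loc[y == "B", "f3"] += 6.0
        res = sequential_select(X, y, "forward", cv_folds=5, mc_reps=3, seed=0)
        assert res.trace["history"][1][0] == [3]  # first move adds f3

    def test_backward_drops_noise_before_signal(self, rng):
        """Whenever backward selection removes anything, the pure-noise
        feature goes first; it is removed in a majority of seeds."""
        noise_removed = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 100
            X = pd.DataFrame(
                r.standard_normal((2 * n, 6)), columns=[f"f{i}" for i in range(6)]
            )
            y = np.array(["A"] * n + ["B"] * n)
            X.loc[y == "B", ["f0", "f1"]] += 1.0
            res = sequential_select(
                X, y, "backward", start_set=["f0", "f1", "f5"],
                cv_folds=5, mc_reps=5, seed=seed,
            )
            assert set(res.selected) <= {"f0", "f1", "f5"}  # subset of start
            hist = res.trace["history"]
            if len(hist) > 1:
                first_removed = (set(hist[0][0]) - set(hist[1][0])).pop()
                assert first_removed == 5
                noise_removed += 1
        assert noise_removed >= 3

    def test_forward_without_signal_terminates_near_chance(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 8)), columns=[f"f{i}" for i in range(8)])
        y = np.array(["A"] * 20 + ["B"] * 20)
        res = sequential_select(X, y, "forward", cv_folds=5, mc_reps=2, seed=1)
        assert len(res.selected) <= 3
        assert res.trace["criterion"] <= 0.5 + 1e-9

    def test_direction_contracts(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        y = np.array(["A"] * 10 + ["B"] * 10)
        with pytest.raises(ValueError):
            sequential_select(X, y, "forward", start_set=["a"])
        with pytest.raises(ValueError):
            sequential_select(X, y, "backward", start_set=None)
        with pytest.raises(ValueError):
            sequential_select(X, y, "sideways")


class TestPcaSelect:
    def test_two_direction_data_two_components(self, rng):
        t = rng.standard_normal((200, 2))
        X = pd.DataFrame(
            np.column_stack([t[:, 0], t[:, 1], t[:, 0] + t[:, 1], t[:, 0] - t[:, 1]]),
            columns=list("abcd"),
        )
        res = pca_select(X)
        assert len(res.selected) == 2

    def test_isotropic_noise_needs_most_components(self, rng):
        d = 20
        X = pd.DataFrame(rng.standard_normal((4000, d)), columns=[f"f{i}" for i in range(d)])
        res = pca_select(X)
        assert abs(len(res.selected) - int(np.ceil(0.95 * d))) <= 1

    def test_threshold_minimality(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 10)) * np.arange(1, 11), columns=[f"f{i}" for i in range(10)])
        res = pca_select(X)
        ratios = np.array(res.trace["explained_variance_ratio"])
        assert ratios.sum() >= 0.95
        assert ratios[:-1].sum() < 0.95

    def test_loadings_orthonormal_and_sex_passthrough(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 6)), columns=[f"f{i}" for i in range(6)])
        X["demo:sex"] = rng.integers(0, 2, size=50).astype(float)
        res = pca_select(X)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L @ L.T, np.eye(L.shape[0]), atol=1e-10)
        out = res.apply(X)
        assert "demo:sex" in out.columns
        assert out.shape[1] == len(res.selected) + 1

    def test_zero_variance_rejected(self):
        X = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            pca_select(X)


class TestStandardize:
    def test_train_mean_zero_sd_one(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)) * 10 + 5, columns=list("abcd"))
        (out,) = standardize_features(X)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-12)

    def test_heldout_uses_train_statistics(self, rng):
        tr = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        iv = pd.DataFrame(rng.standard_normal((10, 3)) + 2.0, columns=list("abc"))
        _, iv_std = standardize_features(tr, iv)
        assert np.abs(iv_std.mean()).min() > 0.5  # shift survives: no leakage

    def test_constant_feature_flagged_and_zeroed(self, rng):
        tr = pd.DataFrame({"c": np.ones(20), "x": rng.standard_normal(20)})
        (out,) = standardize_features(tr)
        assert out.attrs["constant_features"] == ["c"]
        np.testing.assert_allclose(out["c"], 0.0)

    def test_categorical_sex_exempt(self, rng):
        tr = pd.DataFrame(
            {"demo:sex": [0.0, 1.0] * 10, "x": rng.standard_normal(20) * 9}
        )
        (out,) = standardize_features(tr)
        np.testing.assert_array_equal(out["demo:sex"], tr["demo:sex"])
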