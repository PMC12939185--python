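"""Normalization, LASSO retention, correlation pruning, retention records."""

import numpy as np
import pandas as pd
import pytest

from scatteromics.selection import (
    correlation_prune,
    lasso_select,
    retention_probabilities,
    select_features,
    spearman_matrix,
    zscore_fit_apply,
)


def table(arr, cols=None) -> pd.DataFrame:
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestZScore:
    def test_training_columns_are_standardized(self):
        rng = np.random.default_rng(0)
        train = table(rng.normal(5, 3, size=(50, 4)))
        norm, _, state = zscore_fit_apply(train)
        assert np.all(np.abs(norm.mean()) < 1e-12)
        assert np.allclose(norm.std(ddof=0), 1.0, atol=1e-12)

    def test_test_tables_use_training_parameters(self):
        rng = np.random.default_rng(1)
        train = table(rng.normal(0, 1, size=(100, 3)))
        test = train + 10.0
        _, [test_norm], state = zscore_fit_apply(train, test)
        expected = 10.0 / train.std(ddof=0).values
        assert np.allclose(test_norm.mean().values, expected, atol=0.05)

    def test_constant_feature_flagged_and_excluded(self):
        t = table(np.column_stack([np.ones(20), np.arange(20.0)]), ["c", "v"])
        norm, _, state = zscore_fit_apply(t)
        assert state.constant_features == ["c"]
        assert list(norm.columns) == ["v"]


class TestLassoSelect:
    def test_informative_feature_retained_across_seeds(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 100)
            x = rng.normal(size=(200, 21))
            x[:, 0] = y + 0.1 * rng.normal(size=200)  # informative + tiny noise
            X = table(x)
            norm, _, _ = zscore_fit_apply(X)
            retained, _, _ = lasso_select(norm, y, seed=seed)
            hits += "f0" in retained
        assert hits >= int(0.95 * n_seeds)

    def test_full_shrinkage_gives_empty_retention(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 50)
        X = table(rng.normal(size=(100, 10)))
        retained, _, _ = lasso_select(X, y, seed=0, lambdas=np.array([10.0]))
        assert retained == []

    def test_duplicated_informative_pair_keeps_at_least_one(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 100)
        sig = y + 0.1 * rng.normal(size=200)
        x = rng.normal(size=(200, 12))
        x[:, 0] = sig
        x[:, 1] = sig + 1e-6 * rng.normal(size=200)
        norm, _, _ = zscore_fit_apply(table(x))
        retained, _, _ = lasso_select(norm, y, seed=1)
        assert {"f0", "f1"} & set(retained)

    def test_single_class_rejected(self):
        X = table(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError):
            lasso_select(X, np.zeros(20, dtype=int), seed=0)


class TestSpearmanMatrix:
    def test_monotone_transform_gives_unit_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.random(200)
        m = spearman_matrix(table(np.column_stack([x, np.exp(3 * x)]), ["a", "b"]))
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(m), 1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(50.0)
        m = spearman_matrix(table(np.column_stack([x, x[::-1]]), ["a", "b"]))
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_columns_have_small_correlation(self):
        rng = np.random.default_rng(5)
        m = spearman_matrix(table(rng.random((1000, 4))))
        off = m.values[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(6)
        m = spearman_matrix(table(rng.normal(size=(60, 6))))
        assert np.allclose(m.values, m.values.T)
        assert np.nanmax(np.abs(m.values)) <= 1.0


class TestCorrelationPrune:
    def _setup(self, rhos: dict, ranges: dict):
        names = sorted(ranges)
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for (a, b), r in rhos.items():
            mat.loc[a, b] = mat.loc[b, a] = r
        raw = pd.DataFrame({n: [0.0, ranges[n]] for n in names})
        return names, mat, raw

    def test_smaller_range_member_removed(self):
        names, mat, raw = self._setup({("a", "b"): 0.9}, {"a": 5.0, "b": 2.0})
        final, removed = correlation_prune(names, mat, raw)
        assert final == ["a"]
        assert removed == [("b", "a", 0.9)]

    def test_boundary_rho_is_strict(self):
        names, mat, raw = self._setup({("a", "b"): 0.79}, {"a": 5.0, "b": 2.0})
        final, _ = correlation_prune(names, mat, raw)
        assert final == ["a", "b"]

    def test_three_way_cluster_keeps_largest_range(self):
        names, mat, raw = self._setup(
            {("a", "b"): 0.95, ("a", "c"): 0.9, ("b", "c"): 0.85},
            {"a": 3.0, "b": 2.0, "c": 1.0},
        )
        final, _ = correlation_prune(names, mat, raw)
        assert final == ["a"]

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(50, 1))
        x = np.hstack([base + 0.1 * rng.normal(size=(50, 3)), rng.normal(size=(50, 3))])
        X = table(x)
        mat = spearman_matrix(X)
        once, _ = correlation_prune(list(X.columns), mat, X)
        twice, _ = correlation_prune(once, mat, X)
        assert once == twice

    def test_negative_correlation_also_pruned(self):
        names, mat, raw = self._setup({("a", "b"): -0.9}, {"a": 1.0, "b": 2.0})
        final, _ = correlation_prune(names, mat, raw)
        assert final == ["b"]

    def test_empty_input(self):
        final, removed = correlation_prune([], pd.DataFrame(), pd.DataFrame())
        assert final == [] and removed == []


class TestSelectFeaturesPipeline:
    def test_selection_depends_only_on_training_data(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 30)
        x = rng.normal(size=(60, 10))
        x[:, 2] += 2 * y
        X = table(x)
        s1 = select_features(X, y, seed=11)
        s2 = select_features(X.copy(), y.copy(), seed=11)
        assert s1.final_features == s2.final_features
        assert np.array_equal(s1.lasso_coefficients.values, s2.lasso_coefficients.values)
        assert s1.lasso_lambda == s2.lasso_lambda

    def test_informative_feature_survives_pipeline(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 40)
        x = rng.normal(size=(80, 8))
        x[:, 0] += 3 * y
        state = select_features(table(x), y, seed=3)
        assert "f0" in state.final_features
        assert set(state.final_features) <= set(state.retained_after_lasso)

    def test_null_features_rarely_retained(self):
        # under label-independent features, each feature's retention across
        # independent selections stays far from certainty
        counts = {}
        n_runs = 8
        for seed in range(n_runs):
            rng = np.random.default_rng(100 + seed)
            y = np.repeat([0, 1], 30)
            state = select_features(table(rng.normal(size=(60, 20))), y, seed=seed)
            for f in state.final_features:
                counts[f] = counts.get(f, 0) + 1
        assert max(counts.values(), default=0) <= int(0.75 * n_runs)


class TestRetentionProbabilities:
    def test_arithmetic(self):
        records = [["a"]] * 150 + []
        probs = retention_probabilities(records, ["a", "b"], n_cycles=150)
        assert probs["a"] == 1.0
        assert probs["b"] == 0.0

    def test_half_retention(self):
        records = [["x"]] * 75 + [[]] * 75
        probs = retention_probabilities(records, ["x"], n_cycles=150)
        assert probs["x"] == 0.5

    def test_sorted_descending(self):
        records = [["a", "b"], ["a"], ["a", "c"]]
        probs = retention_probabilities(records, ["a", "b", "c", "d"])
        assert list(probs.index)[0] == "a"
        assert probs.is_monotonic_decreasing

    def test_requires_cycles(self):
        with pytest.raises(ValueError):
            retention_probabilities([], ["a"])
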