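"""Cross-validation protocol: folds, training, thresholding, determinism."""

import numpy as np
import pytest

from scatteromics.modeling import (
    CVConfig,
    apply_model,
    cv_cycle_plan,
    repeated_cv,
    stratified_kfold,
    train_classifier,
    youden_threshold,
)

from conftest import synthetic_feature_table

SMALL_CONFIG = CVConfig(
    n_folds=5,
    n_repeats=2,
    svm_kernels=("linear",),
    svm_c=(1.0,),
    rf_trees=(50,),
    rf_min_leaf=(2,),
    inner_folds=3,
    lasso_lambdas=tuple(np.logspace(-3, 0, 15)),
)


class TestStratifiedKFold:
    def test_balanced_partition(self):
        y = np.array([0] * 60 + [1] * 40)
        folds = stratified_kfold(y, 5, seed=0)
        for _, va in folds:
            assert len(va) == 20
            assert np.sum(y[va] == 0) == 12 and np.sum(y[va] == 1) == 8

    def test_partition_property(self):
        y = np.array([0] * 33 + [1] * 17)
        folds = stratified_kfold(y, 5, seed=1)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(50))
        for i, (_, va) in enumerate(folds):
            for j, (_, vb) in enumerate(folds):
                if i != j:
                    assert np.intersect1d(va, vb).size == 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.zeros(20, dtype=int), 5, seed=0)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0] * 20 + [1] * 3), 5, seed=0)

    def test_deterministic_per_seed(self):
        y = np.array([0] * 30 + [1] * 20)
        f1 = stratified_kfold(y, 5, seed=9)
        f2 = stratified_kfold(y, 5, seed=9)
        assert all(np.array_equal(a[1], b[1]) for a, b in zip(f1, f2))


def test_default_protocol_has_150_cycles():
    y = np.array([0] * 75 + [1] * 50)
    plan = cv_cycle_plan(y, CVConfig(), seed=0)
    assert len(plan) == 150
    assert CVConfig().n_cycles == 150


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["svm", "rf", "lda"])
    def test_separable_toy_reaches_perfect_training_accuracy(self, kind):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        x = rng.normal(size=(40, 3))
        x[:, 0] += 10 * y  # widely separated
        model = train_classifier(kind, x, y, SMALL_CONFIG, seed=1)
        probs = model.estimator.predict_proba(x)[:, 1]
        assert np.mean((probs > 0.5) == y) == 1.0

    def test_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 15)
        x = rng.normal(size=(30, 4))
        for kind in ("svm", "rf", "lda"):
            p = train_classifier(kind, x, y, SMALL_CONFIG, seed=2).estimator.predict_proba(x)
            assert np.all((p >= 0) & (p <= 1))

    def test_hyperparameter_choice_deterministic(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 25)
        x = rng.normal(size=(50, 5))
        x[:, 1] += 1.2 * y
        cfg = CVConfig(
            n_repeats=1, svm_kernels=("linear", "rbf"), svm_c=(0.1, 1.0, 10.0),
            rf_trees=(50, 100), rf_min_leaf=(1, 5), inner_folds=3,
        )
        h1 = train_classifier("svm", x, y, cfg, seed=5).hyperparameters
        h2 = train_classifier("svm", x, y, cfg, seed=5).hyperparameters
        assert h1 == h2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            train_classifier("mlp", np.zeros((10, 2)), np.repeat([0, 1], 5), SMALL_CONFIG, 0)


class TestYoudenThreshold:
    def test_perfect_split(self):
        res = youden_threshold([0.2, 0.6, 0.9], [0, 1, 1])
        assert res.threshold == pytest.approx(0.4)
        assert res.j == pytest.approx(1.0)
        assert not res.degenerate

    def test_constant_scores_flagged_degenerate(self):
        res = youden_threshold([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert res.degenerate and res.j == 0.0

    def test_null_scores_have_small_j(self):
        rng = np.random.default_rng(3)
        scores = rng.random(1000)
        labels = np.repeat([0, 1], 500)
        res = youden_threshold(scores, labels)
        # max-J over cutpoints is a two-sample KS statistic; null scale
        # ~ 1.36 sqrt(2/500) at the 5% point
        assert res.j < 0.12

    def test_ties_resolve_to_lowest_threshold(self):
        # two cutpoints achieve J = 1; the lower must win
        res = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.threshold == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.9], [1, 1])


class TestRepeatedCV:
    def test_cycle_count_and_leakage_guard(self):
        table = synthetic_feature_table(n_subjects=30, seed=1)
        res = repeated_cv(table, SMALL_CONFIG, seed=4)
        assert res.n_cycles == 10
        for c in res.cycles:
            assert np.intersect1d(c.train_idx, c.val_idx).size == 0
            assert len(c.train_idx) + len(c.val_idx) == 30

    def test_separable_cohort_scores_high(self):
        table = synthetic_feature_table(n_subjects=40, seed=2, effect=3.0)
        res = repeated_cv(table, SMALL_CONFIG, seed=5)
        for kind in ("svm", "rf", "lda"):
            assert np.median(res.cycle_aurocs(kind)) > 0.9

    def test_bit_reproducible(self):
        table = synthetic_feature_table(n_subjects=24, seed=3, effect=1.0)
        r1 = repeated_cv(table, SMALL_CONFIG, seed=6)
        r2 = repeated_cv(table, SMALL_CONFIG, seed=6)
        for c1, c2 in zip(r1.cycles, r2.cycles):
            assert c1.final_features == c2.final_features
            for kind in SMALL_CONFIG.classifiers:
                assert c1.metrics[kind] == c2.metrics[kind]
                assert np.array_equal(c1.val_probabilities[kind], c2.val_probabilities[kind])

    def test_retention_counts_bounded_by_cycles(self):
        table = synthetic_feature_table(n_subjects=24, seed=4)
        res = repeated_cv(table, SMALL_CONFIG, seed=7)
        assert (res.retention_counts >= 0).all()
        assert (res.retention_counts <= res.n_cycles).all()


class TestApplyModel:
    def _fitted(self):
        table = synthetic_feature_table(n_subjects=30, seed=5, effect=2.5)
        res = repeated_cv(table, SMALL_CONFIG, seed=8)
        return table, res.best_models["lda"]

    def test_training_table_reproduces_predictions(self):
        table, model = self._fitted()
        p1, c1 = apply_model(model, table)
        p2, c2 = apply_model(model, table)
        assert np.array_equal(p1, p2) and np.array_equal(c1, c2)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert set(np.unique(c1)) <= {0, 1}

    def test_single_row(self):
        table, model = self._fitted()
        p, c = apply_model(model, table.iloc[[0]])
        assert p.shape == (1,) and c.shape == (1,)

    def test_missing_feature_columns_rejected(self):
        table, model = self._fitted()
        bad = table.drop(columns=model.selection.final_features[:1])
        with pytest.raises(ValueError, match="missing feature"):
            apply_model(model, bad)

    def test_held_out_cohort_close_to_validation(self):
        # exchangeable synthetic cohorts: test AUROC within sampling noise
        train = synthetic_feature_table(n_subjects=60, seed=6, effect=2.0)
        test = synthetic_feature_table(n_subjects=60, seed=106, effect=2.0)
        res = repeated_cv(train, SMALL_CONFIG, seed=9)
        from scatteromics.evaluation import auroc

        for kind in ("svm", "lda"):
            probs, _ = apply_model(res.best_models[kind], test)
            a = auroc(probs, test["label"].to_numpy()).value
            med = np.median(res.cycle_aurocs(kind))
            assert abs(a - med) < 0.25
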