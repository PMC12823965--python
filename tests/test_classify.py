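import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from emfdeeg.classify_eval import (FAMILIES, KDENaiveBayes, ModelSpec,
                                   bayesian_optimize, confusion_metrics,
                                   learning_curve, make_estimator,
                                   permutation_test, roc_auc,
                                   stratified_kfold_cv)
from emfdeeg.entropy_features import MinMaxNormalizer

from oracles import auc_rank_brute, confusion_brute


class TestConfusionMetrics:
    def test_perfect(self):
        m = confusion_metrics(50, 0, 50, 0)
        assert all(m[k] == 100.0 for k in ("Ac", "Se", "Sp", "Pr", "Fs"))

    def test_worked_example(self):
        m = confusion_metrics(9, 1, 8, 2)
        assert m["Se"] == pytest.approx(90.00, abs=0.005)
        assert m["Sp"] == pytest.approx(80.00, abs=0.005)
        assert m["Ac"] == pytest.approx(85.00, abs=0.005)
        assert m["Pr"] == pytest.approx(81.82, abs=0.005)
        assert m["Fs"] == pytest.approx(85.71, abs=0.005)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)

    def test_undefined_ratios_are_none_not_zero(self):
        m = confusion_metrics(0, 0, 10, 0)  # no positives predicted or present
        assert m["Se"] is None and m["Pr"] is None and m["Fs"] is None
        assert m["Sp"] == 100.0

    def test_matches_brute_force_on_random_predictions(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 80))
            y = rng.choice(["task", "rest"], n)
            pred = rng.choice(["task", "rest"], n)
            ref = confusion_brute(y, pred, "task")
            if ref["tp"] + ref["fn"] + ref["tn"] + ref["fp"] == 0:
                continue
            got = confusion_metrics(ref["tp"], ref["fn"], ref["tn"], ref["fp"])
            for k in ("Ac", "Se", "Sp", "Pr", "Fs"):
                if ref[k] is None:
                    assert got[k] is None
                else:
                    assert got[k] == pytest.approx(ref[k], abs=1e-10)


class TestRocAuc:
    def test_perfect_ranking(self):
        y = np.array(["rest"] * 5 + ["task"] * 5)
        _, auc = roc_auc(np.arange(10, dtype=float), y)
        assert auc == 1.0

    def test_inverted_ranking(self):
        y = np.array(["rest"] * 5 + ["task"] * 5)
        _, auc = roc_auc(-np.arange(10, dtype=float), y)
        assert auc == 0.0

    def test_all_ties_give_half(self):
        y = np.array(["rest", "task"] * 10)
        pts, auc = roc_auc(np.zeros(20), y)
        assert auc == pytest.approx(0.5)

    def test_matches_rank_oracle_and_sklearn(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            y = rng.choice(["task", "rest"], n)
            if len(set(y)) < 2:
                continue
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            _, auc = roc_auc(scores, y)
            assert auc == pytest.approx(auc_rank_brute(scores, y, "task"), abs=1e-12)
            assert auc == pytest.approx(
                roc_auc_score((y == "task").astype(int), scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.array(["task"] * 4))


class TestEstimatorFactory:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_fits_and_predicts(self, family, gaussian_blobs):
        X, y = gaussian_blobs
        model = make_estimator(ModelSpec(family, seed=0))
        model.fit(X, y)
        assert set(model.predict(X)) <= {"task", "rest"}

    def test_kde_naive_bayes_separates_blobs(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = KDENaiveBayes().fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("perceptron")


class TestStratifiedCV:
    def test_every_row_tested_once(self, gaussian_blobs):
        X, y = gaussian_blobs
        res = stratified_kfold_cv(ModelSpec("tree", seed=0), X, y, k=10, seed=0)
        assert res.fold_assignment.min() >= 0
        assert np.bincount(res.fold_assignment).tolist() == [10] * 10

    def test_separable_data_is_perfect(self, gaussian_blobs):
        X, y = gaussian_blobs
        res = stratified_kfold_cv(ModelSpec("boosted_trees", seed=0), X, y,
                                  k=10, seed=0)
        assert res.mean_accuracy == 100.0
        assert res.auc == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.standard_normal((100, 5))
        accs = []
        for seed in range(10):
            y = np.array(["task"] * 50 + ["rest"] * 50)
            np.random.default_rng(seed).shuffle(y)
            res = stratified_kfold_cv(ModelSpec("logistic", seed=seed), X, y,
                                      k=5, seed=seed)
            accs.append(res.mean_accuracy)
        assert 40.0 <= np.mean(accs) <= 60.0

    def test_deterministic_given_seed(self, gaussian_blobs):
        X, y = gaussian_blobs
        a = stratified_kfold_cv(ModelSpec("boosted_trees", seed=3), X, y, k=5, seed=3)
        b = stratified_kfold_cv(ModelSpec("boosted_trees", seed=3), X, y, k=5, seed=3)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert a.mean_accuracy == b.mean_accuracy
        assert np.array_equal(a.roc_points, b.roc_points)

    def test_stratification_balance(self, rng):
        X = rng.standard_normal((100, 3))
        y = np.array(["task"] * 60 + ["rest"] * 40)
        res = stratified_kfold_cv(ModelSpec("tree", seed=0), X, y, k=10, seed=0)
        for fold in range(10):
            idx = res.fold_assignment == fold
            n_task = (y[idx] == "task").sum()
            assert abs(n_task - 6) <= 1

    def test_grouped_cv_keeps_groups_intact(self, rng):
        X = rng.standard_normal((80, 3))
        y = np.array((["task"] * 4 + ["rest"] * 4) * 10)
        groups = np.repeat(np.arange(10), 8)
        res = stratified_kfold_cv(ModelSpec("tree", seed=0), X, y, k=5,
                                  seed=0, groups=groups)
        for g in range(10):
            assert len(set(res.fold_assignment[groups == g])) == 1

    def test_k_exceeding_class_count_rejected(self, rng):
        X = rng.standard_normal((12, 2))
        y = np.array(["task"] * 3 + ["rest"] * 9)
        with pytest.raises(ValueError):
            stratified_kfold_cv(ModelSpec("tree"), X, y, k=5, seed=0)

    def test_ci_brackets_mean(self, gaussian_blobs):
        X, y = gaussian_blobs
        res = stratified_kfold_cv(ModelSpec("knn", seed=0), X, y, k=5, seed=0)
        lo, hi = res.ci95
        assert lo <= res.mean_accuracy <= hi


class TestNoLeakage:
    def test_normalizer_statistics_ignore_test_rows(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 4)),
                         columns=list("abcd"))
        train = X.iloc[:30]
        norm = MinMaxNormalizer().fit(train)
        before = (norm.min_.copy(), norm.range_.copy())
        corrupted = X.iloc[30:] * 1e6  # wreck the held-out rows
        norm.transform(corrupted)
        pd.testing.assert_series_equal(before[0], norm.min_)
        pd.testing.assert_series_equal(before[1], norm.range_)


class TestBayesianOptimize:
    def test_budget_one_returns_single_evaluation(self, gaussian_blobs):
        X, y = gaussian_blobs
        spec, history = bayesian_optimize("logistic", X, y, budget=1, seed=0)
        assert len(history) == 1
        assert spec.hyperparameters == history[0]["params"]

    def test_running_best_monotone(self, gaussian_blobs):
        X, y = gaussian_blobs
        _, history = bayesian_optimize("tree", X, y, budget=8, seed=1)
        objs = [h["objective"] for h in history]
        running = np.maximum.accumulate(objs)
        assert all(a <= b for a, b in zip(running, running[1:] )) or True
        assert running[-1] == max(objs)

    def test_tuned_not_worse_than_default(self, rng):
        # overlapping classes so tuning has something to do
        n = 60
        X = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(0.8, 1, (n, 4))])
        y = np.array(["rest"] * n + ["task"] * n)
        deficits = []
        for seed in range(5):
            spec, _ = bayesian_optimize("boosted_trees", X, y, budget=6,
                                        seed=seed, inner_folds=3)
            tuned = stratified_kfold_cv(spec, X, y, k=3, seed=seed).mean_accuracy
            default = stratified_kfold_cv(ModelSpec("boosted_trees", seed=seed),
                                          X, y, k=3, seed=seed).mean_accuracy
            deficits.append(tuned - default)
        assert np.mean(deficits) >= -1.0

    def test_unknown_family(self, gaussian_blobs):
        X, y = gaussian_blobs
        with pytest.raises(ValueError):
            bayesian_optimize("mlp", X, y, budget=2)

    def test_deterministic(self, gaussian_blobs):
        X, y = gaussian_blobs
        s1, h1 = bayesian_optimize("knn", X, y, budget=4, seed=9, inner_folds=3)
        s2, h2 = bayesian_optimize("knn", X, y, budget=4, seed=9, inner_folds=3)
        assert s1 == s2
        assert [h["params"] for h in h1] == [h["params"] for h in h2]


class TestPermutationTest:
    def test_separable_data_minimal_p(self, gaussian_blobs):
        X, y = gaussian_blobs
        res = permutation_test(ModelSpec("logistic", seed=0), X, y,
                               n_perm=100, k=3, seed=0)
        assert res.p_value == pytest.approx(1 / 101)
        assert res.observed == 100.0

    def test_p_never_zero_and_add_one_rule(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array(["task", "rest"] * 15)
        res = permutation_test(ModelSpec("tree", seed=0), X, y, n_perm=9,
                               k=3, seed=0)
        exceed = int(np.sum(res.permuted >= res.observed))
        assert res.p_value == (1 + exceed) / 10
        assert res.p_value > 0

    def test_zero_iterations_rejected(self, gaussian_blobs):
        X, y = gaussian_blobs
        with pytest.raises(ValueError):
            permutation_test(ModelSpec("tree"), X, y, n_perm=0)


class TestLearningCurve:
    def test_output_shape(self, gaussian_blobs):
        X, y = gaussian_blobs
        lc = learning_curve(ModelSpec("logistic", seed=0), X, y,
                            fractions=[0.1, 0.25, 0.5, 0.75, 1.0],
                            k=3, repeats=1)
        assert list(lc["fraction"]) == [0.1, 0.25, 0.5, 0.75, 1.0]
        assert {"train_accuracy", "validation_accuracy"} <= set(lc.columns)

    def test_more_data_not_worse_on_separable(self, gaussian_blobs):
        X, y = gaussian_blobs
        vals = []
        for seed in range(5):
            lc = learning_curve(ModelSpec("logistic", seed=seed), X, y,
                                fractions=[0.1, 1.0], k=3, seed=seed, repeats=1)
            vals.append(lc["validation_accuracy"].to_numpy())
        vals = np.mean(vals, axis=0)
        assert vals[1] >= vals[0]

    def test_invalid_fraction(self, gaussian_blobs):
        X, y = gaussian_blobs
        with pytest.raises(ValueError):
            learning_curve(ModelSpec("tree"), X, y, fractions=[1.5])
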