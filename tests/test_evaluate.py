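"""Stratified repeated CV, ranking, occurrence tables, PCA baseline."""

import numpy as np
import pandas as pd
import pytest

import hrvbench as hb
from hrvbench.combsearch import Combination
from hrvbench.evaluate import (ClassifierSpec, default_classifiers,
                               feature_occurrence, fit_predict, make_folds,
                               pca_baseline, rank_combinations, repeated_cv)


class TestMakeFolds:
    def test_30_40_cohort_gives_6_8_per_fold(self):
        labels = np.array(["healthy"] * 30 + ["patient"] * 40)
        for seed in range(10):
            fold_id = make_folds(labels, k=5, seed=seed)
            for fold in range(5):
                mask = fold_id == fold
                assert (labels[mask] == "healthy").sum() == 6
                assert (labels[mask] == "patient").sum() == 8

    def test_partition_property(self):
        labels = np.array(["a"] * 17 + ["b"] * 23)
        fold_id = make_folds(labels, k=5, seed=1)
        assert fold_id.size == 40
        assert set(fold_id) == set(range(5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array(["a"] * 20), k=5, seed=0)

    def test_deterministic_given_seed(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        np.testing.assert_array_equal(make_folds(labels, 5, seed=3),
                                      make_folds(labels, 5, seed=3))


class TestFitPredict:
    def test_all_families_separate_blobs(self, blob_table):
        """Well-separated Gaussian blobs: every family ≥ 99% held out."""
        for spec in default_classifiers():
            r = repeated_cv(blob_table, ["a", "b", "c", "d"], spec,
                            repeats=10, seed=5)
            assert r.mean_accuracy >= 99.0, spec.name

    def test_knn_memorizes_training_point(self):
        x = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        spec = ClassifierSpec("NN3", "k-nearest-neighbors", (("k", 3),))
        pred = fit_predict(spec, x, y, np.array([[0.1], [5.1]]))
        assert list(pred) == ["a", "b"]

    def test_chance_level_on_random_labels(self):
        """Labels independent of features: accuracy 50% ± 10% (20 seeds)."""
        rng = np.random.default_rng(0)
        accs = []
        spec = default_classifiers()[0]  # LDA
        for seed in range(20):
            x = rng.standard_normal((40, 3))
            table = pd.DataFrame(x, columns=list("abc"))
            table["label"] = rng.permutation(["h"] * 20 + ["p"] * 20)
            r = repeated_cv(table, list("abc"), spec, repeats=5, seed=seed)
            accs.append(r.mean_accuracy)
        assert abs(np.mean(accs) - 50.0) < 10.0

    def test_single_class_train_rejected(self):
        spec = default_classifiers()[0]
        with pytest.raises(ValueError):
            fit_predict(spec, np.zeros((4, 2)), np.array(["a"] * 4),
                        np.zeros((2, 2)))

    def test_discriminant_fallback_on_tiny_folds(self):
        """Rank-deficient class covariances (3 samples, 4 features) fall back
        to regularized discriminant fits instead of failing."""
        rng = np.random.default_rng(0)
        x = np.vstack([0.2 * rng.standard_normal((3, 4)),
                       0.2 * rng.standard_normal((3, 4)) + 3.0])
        y = np.array(["a"] * 3 + ["b"] * 3)
        for spec in default_classifiers()[:2]:  # LDA, QDA
            pred = fit_predict(spec, x, y, x)
            assert (pred == y).all()

    def test_nonfinite_features_rejected(self):
        spec = default_classifiers()[0]
        x = np.zeros((4, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_predict(spec, x, np.array(["a", "a", "b", "b"]), np.zeros((2, 2)))


class TestRepeatedCV:
    def test_single_repetition_sd_over_folds(self, blob_table):
        spec = default_classifiers()[0]
        r = repeated_cv(blob_table, ["a", "b"], spec, repeats=1, seed=0)
        assert r.n_repeats == 1
        assert r.sd_accuracy >= 0.0

    def test_mean_stable_under_more_repeats(self, blob_table):
        table = blob_table.copy()
        rng = np.random.default_rng(2)
        table[["a", "b", "c", "d"]] += 1.6 * rng.standard_normal((70, 4))
        spec = default_classifiers()[0]
        r1 = repeated_cv(table, list("abcd"), spec, repeats=20, seed=1)
        r2 = repeated_cv(table, list("abcd"), spec, repeats=40, seed=9)
        se = r1.sd_accuracy / np.sqrt(20)
        assert abs(r1.mean_accuracy - r2.mean_accuracy) <= 4 * se

    def test_sd_mode_folds_spreads_wider(self, blob_table):
        table = blob_table.copy()
        rng = np.random.default_rng(3)
        table[["a", "b", "c", "d"]] += 1.8 * rng.standard_normal((70, 4))
        spec = default_classifiers()[0]
        reps = repeated_cv(table, list("abcd"), spec, repeats=10, seed=2)
        folds = repeated_cv(table, list("abcd"), spec, repeats=10, seed=2,
                            sd_mode="folds")
        assert reps.mean_accuracy == folds.mean_accuracy
        assert folds.sd_accuracy >= reps.sd_accuracy

    def test_scaling_rescues_rbf_on_large_scale_features(self, blob_table):
        table = blob_table.copy()
        table[["a", "b", "c", "d"]] *= 50.0  # kernel-hostile raw scale
        svm = default_classifiers()[5]
        raw = repeated_cv(table, list("abcd"), svm, repeats=5, seed=1)
        scaled = repeated_cv(table, list("abcd"), svm, repeats=5, seed=1,
                             scale=True)
        assert scaled.mean_accuracy > raw.mean_accuracy

    def test_deterministic_given_seed(self, blob_table):
        spec = default_classifiers()[5]  # RBF SVM
        a = repeated_cv(blob_table, ["a", "b"], spec, repeats=5, seed=11)
        b = repeated_cv(blob_table, ["a", "b"], spec, repeats=5, seed=11)
        assert (a.mean_accuracy, a.sd_accuracy) == (b.mean_accuracy, b.sd_accuracy)


def _result(classifier, features, mean, sd):
    return hb.CVResult(classifier=classifier,
                       combination=Combination(tuple(features), 0.0),
                       mean_accuracy=mean, sd_accuracy=sd,
                       n_repeats=100, n_folds=5, seed=0)


class TestRankingAndOccurrence:
    def test_ranking_order_and_format(self):
        lda = default_classifiers()[0]
        results = [_result(lda, ("A", "B"), 90.30, 1.37),
                   _result(lda, ("C", "D"), 91.33, 1.75)]
        ranked = rank_combinations(results)
        assert ranked.iloc[0]["score"] == "91.33 ± 1.75"
        assert ranked.iloc[1]["score"] == "90.30 ± 1.37"

    def test_tie_broken_by_lower_sd(self):
        lda = default_classifiers()[0]
        results = [_result(lda, ("A", "B"), 90.0, 2.0),
                   _result(lda, ("C", "D"), 90.0, 1.0)]
        ranked = rank_combinations(results)
        assert ranked.iloc[0]["features"] == "C;D"

    def test_occurrence_percentages(self):
        lda = default_classifiers()[0]
        results = [_result(lda, combo, acc, 1.0) for combo, acc in [
            (("HR", "A", "B", "C"), 92.0),
            (("HR", "A", "D", "E"), 91.0),
            (("F", "G", "H", "I"), 80.0),
        ]]
        occ = feature_occurrence(results, 90.0)
        table = dict(zip(occ["feature"], occ["occurrence_pct"]))
        assert table["HR"] == pytest.approx(100.0)
        assert table["A"] == pytest.approx(100.0)
        assert table["B"] == pytest.approx(50.0)
        assert "F" not in table

    def test_no_combination_passes(self):
        lda = default_classifiers()[0]
        occ = feature_occurrence([_result(lda, ("A", "B"), 70.0, 1.0)], 90.0)
        assert occ.empty


class TestPCABaseline:
    def test_variance_table_properties(self, blob_table):
        table = blob_table.copy()
        rng = np.random.default_rng(4)
        for i in range(12):
            table[f"n{i}"] = rng.standard_normal(70)
        res = pca_baseline(table, n_components=10, sizes=(2,), repeats=2,
                           seed=0, specs=[default_classifiers()[0]])
        expl = res.variance_table["explained_variance_pct"].to_numpy()
        assert expl.sum() == pytest.approx(100.0)
        assert np.all(np.diff(expl) <= 1e-9)
        cum = res.variance_table["cumulative_variance_pct"].to_numpy()
        np.testing.assert_allclose(cum, np.cumsum(expl))

    def test_dominant_direction_recovered(self):
        """A 100:1 variance-ratio construction loads > 90% on PC1."""
        rng = np.random.default_rng(0)
        direction = rng.uniform(0.5, 1.0, 12) * rng.choice([-1, 1], 12)
        direction /= np.linalg.norm(direction)
        scores = 10.0 * rng.standard_normal(80)
        x = np.outer(scores, direction) + 0.1 * rng.standard_normal((80, 12))
        table = pd.DataFrame(x, columns=[f"f{i}" for i in range(12)])
        table["label"] = ["h"] * 40 + ["p"] * 40
        res = pca_baseline(table, n_components=2, sizes=(2,), repeats=1, seed=0,
                           specs=[default_classifiers()[0]])
        assert res.variance_table["explained_variance_pct"].iloc[0] > 90.0

    def test_too_few_features_rejected(self, blob_table):
        with pytest.raises(ValueError):
            pca_baseline(blob_table, n_components=10, sizes=(2,), repeats=1)
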