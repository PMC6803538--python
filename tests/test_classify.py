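"""Feature fusion, Relief-F, grid-searched SVM, repeated CV, modality ANOVA."""

import numpy as np
import pytest

from neurointent.classify import (
    IntentionDecoder,
    ReliefF,
    fuse,
    grid_search_train,
    modality_comparison,
    repeated_cv,
)
from neurointent.network import NodalFeatureTable
from neurointent.sensor_stats import DegenerateDataError

SMALL_C = (2.0**-1, 2.0**3, 2.0**7)
SMALL_G = (2.0**-9, 2.0**-5, 2.0**-1)


def _table(values, labels, modality="EEG", prefix="f"):
    values = np.asarray(values, dtype=float)
    cols = [f"{modality}:{prefix}{i}:metric" for i in range(values.shape[1])]
    return NodalFeatureTable(values=values, columns=cols,
                             labels=np.asarray(labels), modality=modality)


def _blobs(rng, n_per_class=30, sep=6.0):
    X = np.vstack(
        [rng.standard_normal((n_per_class, 2)) + [i * sep, 0] for i in range(3)]
    )
    y = np.repeat(["Sd", "Sm", "Su"], n_per_class)
    return X, y


class TestFuse:
    def test_column_concatenation_counts(self):
        labels = ["Sd", "Sm", "Su"] * 4
        a = _table(np.zeros((12, 320)), labels, "EEG")
        b = _table(np.ones((12, 240)), labels, "HbO")
        fused = fuse(a, b)
        assert fused.values.shape == (12, 560)  # 64*5 + 48*5
        assert fused.columns[:320] == a.columns
        assert np.all(fused.values[:, 320:] == 1.0)

    def test_row_order_preserved(self):
        labels = ["Sd", "Sm", "Su"] * 2
        vals = np.arange(12.0).reshape(6, 2)
        fused = fuse(_table(vals, labels), _table(vals * 10, labels, "HbO"))
        assert np.array_equal(fused.values[:, :2], vals)

    def test_fuse_with_empty_is_identity(self):
        labels = ["Sd", "Su"]
        a = _table(np.ones((2, 3)), labels)
        b = _table(np.empty((2, 0)), labels, "HbO")
        fused = fuse(a, b)
        assert np.array_equal(fused.values, a.values)

    def test_label_mismatch_rejected(self):
        a = _table(np.ones((2, 3)), ["Sd", "Sm"])
        b = _table(np.ones((2, 3)), ["Sm", "Sd"], "HbO")
        with pytest.raises(ValueError, match="labels"):
            fuse(a, b)


class TestReliefF:
    def test_six_instance_worked_example(self):
        """Hand-traced update (k=1, two balanced classes, m = all 6).

        Normalized features (ranges 1.0 and 0.9); for each instance the
        nearest hit and miss are found under Manhattan distance; with two
        balanced classes the miss prior ratio is 1.  Accumulating
        diff/(m*k) terms gives W = (-1/5, 31/54).
        """
        X = np.array(
            [[0.0, 0.10], [0.2, 0.90], [0.4, 0.20],
             [0.6, 0.80], [0.8, 0.30], [1.0, 1.00]]
        )
        y = np.array(["a", "b", "a", "b", "a", "b"])
        rf = ReliefF(n_keep=2, k_neighbors=1).fit(X, y)
        assert rf.weights_ == pytest.approx([-1 / 5, 31 / 54], abs=1e-12)
        assert list(rf.ranking_) == [1, 0]

    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        X[:, 1] = 5.0
        y = np.repeat(["a", "b"], 10)
        with pytest.warns(UserWarning, match="zero-range"):
            rf = ReliefF(n_keep=3, k_neighbors=3).fit(X, y)
        assert rf.weights_[1] == 0.0

    def test_planted_separating_feature_ranks_first(self):
        wins = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = np.repeat(["a", "b", "c"], 20)
            X = rng.standard_normal((60, 51))
            X[:, 0] = np.select(
                [y == "a", y == "b", y == "c"], [0.0, 1.0, 2.0]
            ) + 0.05 * rng.standard_normal(60)
            rf = ReliefF(n_keep=5, k_neighbors=10).fit(X, y)
            wins += rf.ranking_[0] == 0
        assert wins >= 29

    def test_weights_invariant_to_feature_scaling(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5))
        y = np.repeat(["a", "b", "c"], 10)
        w1 = ReliefF(k_neighbors=4).fit(X, y).weights_
        scale = np.array([1e-3, 1.0, 50.0, 7.0, 2e4])
        w2 = ReliefF(k_neighbors=4).fit(X * scale + 3.0, y).weights_
        assert np.allclose(w1, w2, atol=1e-12)

    def test_transform_selects_top_features(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((24, 10))
        y = np.repeat(["a", "b"], 12)
        rf = ReliefF(n_keep=4, k_neighbors=3).fit(X, y)
        assert rf.transform(X).shape == (24, 4)
        assert np.array_equal(rf.top_indices_, np.sort(rf.ranking_[:4]))


class TestGridSearch:
    def test_separable_blobs_perfect_training_fit(self):
        X, y = _blobs(np.random.default_rng(3))
        svm, (c, g) = grid_search_train(X, y, SMALL_C, SMALL_G, seed=0)
        assert (svm.predict(X) == y).mean() == 1.0
        assert c in SMALL_C and g in SMALL_G

    def test_deterministic_choice_on_duplicate_data(self):
        X, y = _blobs(np.random.default_rng(4))
        _, p1 = grid_search_train(X, y, SMALL_C, SMALL_G, seed=9)
        _, p2 = grid_search_train(X, y, SMALL_C, SMALL_G, seed=9)
        assert p1 == p2

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(DegenerateDataError):
            grid_search_train(X, np.repeat("Sd", 10), SMALL_C, SMALL_G)


class TestRepeatedCV:
    def _decoder(self):
        return IntentionDecoder(
            n_keep=2, k_neighbors=3, c_grid=SMALL_C, gamma_grid=SMALL_G,
            inner_folds=3,
        )

    def test_separable_features_give_perfect_accuracy(self):
        X, y = _blobs(np.random.default_rng(5), sep=10.0)
        res = repeated_cv(X, y, n_reps=2, n_folds=5, decoder=self._decoder(),
                          seed=0)
        assert res.mean_accuracy == 1.0
        assert np.array_equal(res.confusion, np.diag([60, 60, 60]))

    def test_confusion_trace_equals_accuracy(self):
        rng = np.random.default_rng(6)
        X, y = _blobs(rng, sep=1.0)
        res = repeated_cv(X, y, n_reps=2, n_folds=5, decoder=self._decoder(),
                          seed=1)
        assert res.confusion_accuracy == pytest.approx(res.mean_accuracy, abs=1e-12)
        assert res.confusion.sum() == 2 * 90

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(7)
        X, y = _blobs(rng, sep=8.0)
        y_perm = rng.permutation(y)
        res = repeated_cv(X, y_perm, n_reps=3, n_folds=5,
                          decoder=self._decoder(), seed=2)
        n = 90 * 3
        ci = 2.6 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(res.mean_accuracy - 1 / 3) <= ci

    def test_no_leakage_from_test_fold(self):
        """Shuffling test-fold labels never changes fitted parameters."""
        rng = np.random.default_rng(8)
        X, y = _blobs(rng, n_per_class=10, sep=3.0)
        from sklearn.model_selection import StratifiedKFold

        tr, te = next(StratifiedKFold(3, shuffle=True, random_state=0).split(X, y))
        dec1 = self._decoder().fit(X[tr], y[tr])
        y2 = y.copy()
        y2[te] = rng.permutation(y2[te])  # corrupt only the test fold
        dec2 = self._decoder().fit(X[tr], y2[tr])
        assert dec1.best_params_ == dec2.best_params_
        assert np.array_equal(dec1.selected_features_, dec2.selected_features_)
        assert np.array_equal(dec1.predict(X[te]), dec2.predict(X[te]))


class TestModalityComparison:
    def test_identical_columns_degenerate(self):
        acc = np.tile(np.linspace(0.5, 0.9, 8)[:, None], (1, 3))
        res = modality_comparison(acc, ["eeg", "fnirs", "fused"])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-20)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(9)
        acc = rng.uniform(0.3, 0.9, (10, 3))
        res = modality_comparison(acc, ["eeg", "fnirs", "fused"])
        cols = [acc[:, j] for j in range(3)]
        grand = acc.mean()
        ssb = sum(len(c) * (c.mean() - grand) ** 2 for c in cols)
        ssw = sum(((c - c.mean()) ** 2).sum() for c in cols)
        f = (ssb / 2) / (ssw / (acc.size - 3))
        assert res.f_statistic == pytest.approx(f, abs=1e-10)
        assert res.df == (2, 27)

    def test_planted_offsets_all_pairs_significant(self):
        rng = np.random.default_rng(10)
        base = rng.normal(0, 0.005, (12, 3))
        acc = base + np.array([0.5, 0.65, 0.8])
        res = modality_comparison(acc, ["fnirs", "eeg", "fused"])
        assert all(p < 0.001 for p in res.pairwise_p.values())
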