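"""Paired-contrast construction, ranking, nested CV, and transfer."""

import numpy as np
import pandas as pd
import pytest

from speechstate.classify import (ContrastData, Standardizer,
                                  binomial_significance, make_contrasts,
                                  nested_lopo_cv, rank_features, standardize,
                                  train_contrast_model, transfer_evaluate,
                                  weight_profile)
from speechstate.studies import simulate_contrasts


def _table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "condition", "task",
                                       "A-x", "A-y"])


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Z, _ = standardize(X)
        assert Z.mean() == pytest.approx(0.0)
        assert Z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_dropped(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        Z, sc = standardize(X)
        assert Z.shape[1] == 1
        assert list(sc.keep_) == [True, False]

    def test_test_rows_use_training_parameters(self):
        Xtr = np.array([[0.0], [2.0]])
        Xte = np.array([[4.0]])
        _, Zte, sc = standardize(Xtr, Xte)
        # (4 - 1) / sd(0,2) with sd = sqrt(2)
        assert Zte[0, 0] == pytest.approx(3 / np.sqrt(2))


class TestMakeContrasts:
    def test_construction_and_negation(self):
        t = _table([["s1", "A", "T", 1.0, 2.0], ["s1", "B", "T", 0.0, 0.0]])
        d = make_contrasts(t, "A", "B", "T")
        np.testing.assert_array_equal(d.X[0], [1.0, 2.0])
        np.testing.assert_array_equal(d.X[1], [-1.0, -2.0])
        assert list(d.y) == [1, -1]

    def test_two_samples_per_subject(self):
        rows = []
        for i in range(5):
            rows += [[f"s{i}", "A", "T", float(i), 0.0],
                     [f"s{i}", "B", "T", 0.0, float(i)]]
        d = make_contrasts(_table(rows), "A", "B", "T")
        assert len(d.X) == 10
        assert d.n_subjects == 5

    def test_incomplete_subject_excluded(self):
        t = _table([["s1", "A", "T", 1.0, 2.0], ["s1", "B", "T", 0.0, 0.0],
                    ["s2", "A", "T", 3.0, 1.0]])
        d = make_contrasts(t, "A", "B", "T")
        assert d.n_subjects == 1

    def test_identical_conditions_give_zero_vectors(self):
        t = _table([["s1", "A", "T", 2.0, 3.0], ["s1", "B", "T", 2.0, 3.0]])
        d = make_contrasts(t, "A", "B", "T")
        assert np.all(d.X == 0)


class TestRankFeatures:
    def test_planted_signal_ranked_first(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            d = rng.standard_normal((20, 10))
            d[:, 3] += 2.0
            X = np.vstack([d, -d])
            y = np.array([1] * 20 + [-1] * 20)
            if rank_features(X, y)[0] == 3:
                hits += 1
        assert hits >= 95

    def test_pure_noise_has_no_persistent_winner(self):
        firsts = set()
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            d = rng.standard_normal((15, 30))
            X, y = np.vstack([d, -d]), np.array([1] * 15 + [-1] * 15)
            firsts.add(int(rank_features(X, y)[0]))
        assert len(firsts) > 5

    def test_antisymmetric_class_means_are_negations(self):
        d = np.random.default_rng(3).standard_normal((8, 4))
        X, y = np.vstack([d, -d]), np.array([1] * 8 + [-1] * 8)
        np.testing.assert_allclose(X[y == 1].mean(0), -X[y == -1].mean(0))


class TestBinomial:
    def test_exact_tail_27_of_31(self):
        expected = 36457 / 2 ** 31
        assert binomial_significance(27, 31) == pytest.approx(expected,
                                                              rel=1e-9)

    def test_all_correct_small_n(self):
        assert binomial_significance(5, 5) == pytest.approx(1 / 32)

    def test_chance_level_not_significant(self):
        assert binomial_significance(10, 20) > 0.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_significance(6, 5)


class TestWeightProfile:
    def test_hand_normalization(self):
        prof = weight_profile(np.array([2.0, -1.0, 1.0]), ["a", "b", "c"])
        assert prof.tolist() == pytest.approx([0.50, 0.25, 0.25])

    def test_single_nonzero_weight(self):
        prof = weight_profile(np.array([0.0, 3.0, 0.0]))
        assert prof.tolist() == pytest.approx([0.0, 1.0, 0.0])

    def test_always_sums_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            w = rng.standard_normal(17)
            assert weight_profile(w).sum() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            weight_profile(np.zeros(4))


class TestNestedCV:
    def test_perfectly_separable_toy_set(self):
        d = np.zeros((6, 5))
        d[:, 0] = 1.0
        X = np.vstack([d, -d])
        y = np.array([1] * 6 + [-1] * 6)
        sids = np.array([f"s{i}" for i in range(6)] * 2)
        data = ContrastData(X, y, sids, [f"f{i}" for i in range(5)],
                            ("A", "B"), "T")
        res = nested_lopo_cv(data, seed=0)
        assert res.accuracy == 1.0

    def test_fold_count_and_cotravel(self):
        data = simulate_contrasts(6, n_features=10, effect=1.0, seed=5)
        res = nested_lopo_cv(data, seed=5)
        assert len(res.folds) == 6
        for fold in res.folds:
            assert sorted(fold.truths) == [-1, 1]

    def test_too_few_subjects_rejected(self):
        data = simulate_contrasts(2, n_features=4, seed=6)
        with pytest.raises(ValueError):
            nested_lopo_cv(data)

    def test_linear_model_antisymmetry(self):
        from sklearn.svm import LinearSVC
        d = np.random.default_rng(7).standard_normal((10, 6))
        X, y = np.vstack([d, -d]), np.array([1] * 10 + [-1] * 10)
        clf = LinearSVC(C=1.0, fit_intercept=False).fit(X, y)
        pred = clf.predict(np.vstack([d, -d]))
        np.testing.assert_array_equal(pred[:10], -pred[10:])


class TestTransfer:
    def test_frozen_model_transfers_to_matched_cohort(self):
        train = simulate_contrasts(14, effect=2.0, seed=10)
        ext = simulate_contrasts(14, effect=2.0, seed=11)
        model = train_contrast_model(train, seed=10)
        acc, p = transfer_evaluate(model, ext)
        internal = nested_lopo_cv(train, seed=10).accuracy
        assert acc >= 0.75
        assert abs(acc - internal) <= 0.2

    def test_null_transfer_near_chance(self):
        train = simulate_contrasts(14, effect=0.0, seed=12)
        ext = simulate_contrasts(14, effect=0.0, seed=13)
        model = train_contrast_model(train, seed=12)
        acc, _ = transfer_evaluate(model, ext)
        assert 0.15 <= acc <= 0.85

    def test_feature_mask_restricts_model(self):
        train = simulate_contrasts(10, n_features=20, effect=1.5,
                                   n_signal=20, seed=14)
        mask = [f"f{i:03d}" for i in range(10)]
        model = train_contrast_model(train, feature_mask=mask, seed=14)
        assert all(n not in mask for n in model.feature_names)
        ext = simulate_contrasts(10, n_features=20, effect=1.5, n_signal=20,
                                 seed=15)
        acc, _ = transfer_evaluate(model, ext)
        assert acc >= 0.6

    def test_missing_external_feature_rejected(self):
        train = simulate_contrasts(6, n_features=8, seed=16)
        model = train_contrast_model(train, seed=16)
        ext = simulate_contrasts(6, n_features=8, seed=17)
        ext.feature_names[0] = "renamed"
        with pytest.raises(ValueError, match="f000"):
            transfer_evaluate(model, ext)
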