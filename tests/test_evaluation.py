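"""Confusion-matrix metrics and stratified cross-validation."""

import warnings

import numpy as np
import pytest
import sklearn.metrics as skm

from csibreathe import (ConfusionMatrix, class_counts, confusion_matrix,
                        kfold_cross_validate, metrics, stratified_folds)
from csibreathe.fixtures import TOY_CONFUSION


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        y = np.array([0, 1, 2, 1, 0])
        cm = confusion_matrix(y, y, 3)
        assert np.array_equal(cm.counts, np.diag([2, 2, 1]))

    def test_cell_percentage_of_total(self):
        # a 302-stream fold with 38 correct in one diagonal cell is 12.6 %
        counts = np.zeros((9, 9), dtype=int)
        counts[3, 3] = 38
        rest = 302 - 38
        counts[0, 0] = rest
        cm = ConfusionMatrix(counts)
        assert cm.total == 302
        assert round(cm.percentages()[3, 3], 1) == 12.6

    def test_counts_match_pairwise_enumeration(self, rng):
        # counting oracle on 1000 random label pairs
        R = 6
        pred = rng.integers(0, R, 1000)
        true = rng.integers(0, R, 1000)
        cm = confusion_matrix(pred, true, R)
        for i in range(R):
            for j in range(R):
                assert cm.counts[i, j] == int(np.sum((pred == i) & (true == j)))
        # rows = predicted: sklearn uses rows = true, so compare transposed
        assert np.array_equal(cm.counts, skm.confusion_matrix(true, pred, labels=range(R)).T)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 3)
        with pytest.raises(ValueError):
            confusion_matrix([0, -1], [0, 1], 3)

    def test_column_normalized_sums_to_100(self, rng):
        cm = confusion_matrix(rng.integers(0, 4, 200), rng.integers(0, 4, 200), 4)
        col = cm.column_normalized().sum(axis=0)
        assert np.allclose(col, 100)


class TestClassCounts:
    def test_toy_matrix_counts(self):
        # rows = predicted: TP_0=3, FP_0=1 (row), FN_0=0 (column), TN_0=2
        cc = class_counts(np.array(TOY_CONFUSION), 0)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (3, 1, 0, 2)
        cc1 = class_counts(np.array(TOY_CONFUSION), 1)
        assert (cc1.tp, cc1.fp, cc1.fn, cc1.tn) == (2, 0, 1, 3)

    def test_diagonal_matrix_no_errors(self):
        C = np.diag([5, 3, 2])
        for r in range(3):
            cc = class_counts(C, r)
            assert cc.fp == 0 and cc.fn == 0

    def test_conservation_identity(self, rng):
        C = rng.integers(0, 20, (5, 5))
        for r in range(5):
            cc = class_counts(C, r)
            assert cc.tp + cc.fp + cc.fn + cc.tn == C.sum()

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError):
            class_counts(np.eye(3, dtype=int), 3)


class TestMetrics:
    def test_toy_matrix_hand_computed_values(self):
        rep = metrics(np.array(TOY_CONFUSION))
        assert rep.accuracy == pytest.approx(5 / 6)
        assert rep.precision[0] == pytest.approx(0.75)
        assert rep.recall[0] == pytest.approx(1.0)
        assert rep.specificity[0] == pytest.approx(2 / 3)
        assert rep.f1[0] == pytest.approx(6 / 7)

    def test_perfect_diagonal_all_ones(self):
        rep = metrics(np.diag([4, 4, 4]))
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert np.all(rep.specificity == 1.0)

    def test_label_permutation_invariance(self, rng):
        pred = rng.integers(0, 5, 500)
        true = rng.integers(0, 5, 500)
        rep = metrics(confusion_matrix(pred, true, 5))
        perm = rng.permutation(5)
        rep_p = metrics(confusion_matrix(perm[pred], perm[true], 5))
        assert rep.accuracy == pytest.approx(rep_p.accuracy)
        assert rep.macro_f1 == pytest.approx(rep_p.macro_f1)
        assert rep.macro_precision == pytest.approx(rep_p.macro_precision)

    def test_matches_sklearn_macro_metrics(self, rng):
        # independent route: sklearn on raw labels vs our matrix formulas
        for trial in range(20):
            r = np.random.default_rng(trial)
            R = int(r.integers(2, 7))
            pred = r.integers(0, R, 300)
            true = r.integers(0, R, 300)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = metrics(confusion_matrix(pred, true, R))
            assert rep.accuracy == pytest.approx(skm.accuracy_score(true, pred))
            assert rep.macro_precision == pytest.approx(
                skm.precision_score(true, pred, average="macro", zero_division=0))
            assert rep.macro_recall == pytest.approx(
                skm.recall_score(true, pred, average="macro", zero_division=0))
            assert rep.macro_f1 == pytest.approx(
                skm.f1_score(true, pred, average="macro", zero_division=0))

    def test_accuracy_equals_matching_fraction(self, rng):
        pred = rng.integers(0, 4, 400)
        true = rng.integers(0, 4, 400)
        rep = metrics(confusion_matrix(pred, true, 4))
        assert rep.accuracy == pytest.approx(np.mean(pred == true))

    def test_zero_denominator_warns_and_reports_zero(self):
        # class 2 never predicted and never true
        C = np.zeros((3, 3), dtype=int)
        C[0, 0] = C[1, 1] = 5
        with pytest.warns(UserWarning):
            rep = metrics(C)
        assert rep.precision[2] == 0.0
        assert rep.recall[2] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(np.zeros((3, 3), dtype=int))


class TestStratifiedFolds:
    def test_partition_is_disjoint_and_complete(self, rng):
        y = rng.integers(0, 5, 137)
        folds = stratified_folds(y, 10, seed=4)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(y)
        assert len(np.unique(all_idx)) == len(y)

    def test_full_scale_fold_sizes_302_and_303(self):
        # 3024 streams, 9 balanced classes, 10 folds
        y = np.repeat(np.arange(9), 336)
        folds = stratified_folds(y, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert min(sizes) == 302
        assert max(sizes) == 303
        assert sum(sizes) == 3024

    def test_per_class_proportions_within_two_samples(self):
        y = np.repeat(np.arange(4), [50, 33, 21, 10])
        folds = stratified_folds(y, 5, seed=1)
        for cls, count in zip(*np.unique(y, return_counts=True)):
            expect = count / 5
            for f in folds:
                got = int(np.sum(y[f] == cls))
                assert abs(got - expect) <= 2

    def test_leave_one_out(self):
        y = np.tile([0, 1], 6)
        folds = stratified_folds(y, 12, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds([0, 1, 0, 1], 1)
        with pytest.raises(ValueError):
            stratified_folds([0, 1, 0], 4)


class _MajorityTrainer:
    """Deterministic stand-in model: always predicts the training mode."""

    def __call__(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.label = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.label)


class _NearestMeanTrainer:
    """1-nearest-class-mean on flattened sequences; fast and reasonable."""

    def __call__(self, X, y):
        X = X.reshape(len(X), -1)
        self.classes = np.unique(y)
        self.means = np.stack([X[y == c].mean(axis=0) for c in self.classes])
        return self

    def predict(self, X):
        X = X.reshape(len(X), -1)
        d = ((X[:, None, :] - self.means[None]) ** 2).sum(axis=2)
        return self.classes[np.argmin(d, axis=1)]


class TestKFold:
    def test_each_sample_tested_exactly_once(self, rng):
        X = rng.standard_normal((60, 4, 1))
        y = np.tile([0, 1, 2], 20)
        res = kfold_cross_validate(X, y, _MajorityTrainer(), k=5, seed=2)
        assert len(res.fold_reports) == 5
        assert res.pooled_confusion.total == 60

    def test_aggregate_statistics_consistent(self, rng):
        X = rng.standard_normal((45, 3, 2))
        y = np.tile([0, 1, 2], 15)
        X[y == 1] += 3.0
        X[y == 2] -= 3.0
        res = kfold_cross_validate(X, y, _NearestMeanTrainer(), k=5, seed=0)
        accs = res.fold_accuracies
        assert res.mean_accuracy == pytest.approx(accs.mean())
        assert res.std_accuracy == pytest.approx(accs.std(ddof=1))
        assert res.min_accuracy == accs.min()
        assert res.max_accuracy == accs.max()
        assert res.fold_ci95[0] <= res.mean_accuracy <= res.fold_ci95[1]
        assert res.binomial_ci95[0] <= res.binomial_ci95[1]
        # separable data: the simple model should be near-perfect
        assert res.mean_accuracy > 0.95

    def test_k_larger_than_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            kfold_cross_validate(rng.standard_normal((4, 2, 1)), [0, 1, 0, 1],
                                 _MajorityTrainer(), k=10)
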