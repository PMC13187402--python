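"""Splitting, training, evaluation and significance machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from facedyn import classifier as clf


class _ConstModel:
    """Predicts one fixed class; for closed-form evaluation checks."""

    def __init__(self, cls, classes):
        self.cls = cls
        self.classes_ = np.asarray(classes)

    def predict(self, X):
        return np.full(len(X), self.cls, dtype=self.classes_.dtype)


class _PerfectModel:
    def __init__(self, labels, classes):
        self.labels = np.asarray(labels)
        self.classes_ = np.asarray(classes)

    def predict(self, X):
        return self.labels


def _balanced_labels(n_per_class, classes=("angry", "happy", "sad")):
    return np.repeat(classes, n_per_class)


class TestSplit:
    def test_228_balanced_gives_183_45(self):
        y = _balanced_labels(76)
        tr, te = clf.split_train_test(y, 0.8, seed=0)
        assert len(tr) == 183 and len(te) == 45
        for cls in np.unique(y):
            assert np.sum(y[tr] == cls) == 61
            assert np.sum(y[te] == cls) == 15

    def test_disjoint_exhaustive(self):
        y = _balanced_labels(10)
        tr, te = clf.split_train_test(y, 0.8, seed=1)
        assert set(tr) & set(te) == set()
        assert len(tr) + len(te) == len(y)

    def test_full_fraction_empty_test(self):
        tr, te = clf.split_train_test(_balanced_labels(5), 1.0, seed=0)
        assert len(te) == 0

    def test_same_seed_same_split(self):
        y = _balanced_labels(20)
        assert np.array_equal(clf.split_train_test(y, 0.8, seed=3)[0],
                              clf.split_train_test(y, 0.8, seed=3)[0])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            clf.split_train_test(np.array(["a", "b", "b"]), 0.8)


def _separable(rng, n_per_class=20, scale=0.1):
    centers = np.array([[0, 0, 4], [4, 0, 0], [0, 4, 0]], dtype=float)
    X, y = [], []
    for c, name in zip(centers, ("angry", "happy", "sad")):
        X.append(c + scale * rng.standard_normal((n_per_class, 3)))
        y.extend([name] * n_per_class)
    return np.vstack(X), np.array(y)


class TestTrainClassifier:
    def test_separable_data_high_cv_accuracy(self, rng):
        X, y = _separable(rng)
        search = clf.train_classifier(X, y, seed=0)
        assert search.best_score_ >= 0.95

    @pytest.mark.parametrize("seed", range(5))
    def test_shuffled_labels_near_chance(self, seed):
        rng = np.random.default_rng(seed)
        X, y = _separable(rng, n_per_class=15)
        y = rng.permutation(y)
        search = clf.train_classifier(X, y, seed=seed, cv_folds=3)
        assert 0.2 <= search.best_score_ <= 0.47

    def test_deterministic_predictions(self, rng):
        X, y = _separable(rng)
        p1 = clf.train_classifier(X, y, seed=5).predict(X)
        p2 = clf.train_classifier(X, y, seed=5).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            clf.train_classifier(rng.random((10, 2)), np.zeros(10))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = _balanced_labels(15)
        model = _PerfectModel(y, np.unique(y))
        rep = clf.evaluate(model, np.zeros((45, 2)), y, n_perm=100)
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert all(v == 1.0 for v in rep.balanced_accuracy_per_class.values())
        assert np.trace(rep.confusion) == 45

    def test_constant_prediction_closed_form(self):
        y = _balanced_labels(15)
        model = _ConstModel("angry", np.unique(y))
        rep = clf.evaluate(model, np.zeros((45, 2)), y, n_perm=100)
        assert rep.accuracy == pytest.approx(1 / 3)
        assert rep.kappa == pytest.approx(0.0)
        assert rep.no_information_rate == pytest.approx(15 / 45)

    def test_confusion_row_sums_match_class_counts(self, rng):
        y = _balanced_labels(10)
        pred = rng.choice(np.unique(y), size=len(y))
        rep = clf.evaluate(_PerfectModel(pred, np.unique(y)),
                           np.zeros((30, 1)), y, n_perm=100)
        assert np.array_equal(rep.confusion.sum(axis=1), [10, 10, 10])
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum())

    def test_unseen_test_label_rejected(self):
        model = _ConstModel("a", ["a", "b"])
        with pytest.raises(ValueError):
            clf.evaluate(model, np.zeros((2, 1)), np.array(["a", "zzz"]),
                         n_perm=100)


class TestBinomial:
    def test_closed_forms(self):
        assert clf.binomial_significance(10, 10, 0.5) == pytest.approx(
            0.0009765625)
        assert clf.binomial_significance(0, 7, 0.3) == 1.0

    def test_exact_sum_oracle_45_41(self):
        n, k, p0 = 45, 41, 1 / 3
        brute = sum(comb(n, i, exact=True) * p0**i * (1 - p0) ** (n - i)
                    for i in range(k, n + 1))
        assert clf.binomial_significance(k, n, p0) == pytest.approx(
            brute, rel=1e-10)

    def test_monotone_decreasing_in_successes(self):
        ps = [clf.binomial_significance(k, 20, 1 / 3) for k in range(21)]
        assert np.all(np.diff(ps) < 0)

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            clf.binomial_significance(1, 2, 1.5)


class TestPermutation:
    def test_perfect_classifier_minimum_p(self, rng):
        X, y = _separable(rng)
        model = _PerfectModel(y, np.unique(y))
        p = clf.permutation_significance(model, X, y, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_constant_model_non_significant(self):
        y = _balanced_labels(15)
        model = _ConstModel("angry", np.unique(y))
        p = clf.permutation_significance(model, np.zeros((45, 1)), y,
                                         n_perm=300, seed=1)
        assert p >= 0.4

    def test_agrees_with_binomial(self, rng):
        """Permutation and binomial p-values agree within Monte-Carlo error."""
        y = _balanced_labels(15)
        pred = y.copy()
        flip = rng.choice(45, size=10, replace=False)
        pred[flip] = np.roll(np.unique(y), 1)[
            np.searchsorted(np.unique(y), pred[flip])]
        model = _PerfectModel(pred, np.unique(y))
        rep = clf.evaluate(model, np.zeros((45, 1)), y, n_perm=2000, seed=2)
        assert rep.p_permutation == pytest.approx(rep.p_binomial, abs=0.03)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            clf.permutation_significance(None, None, None, n_perm=10)


def _fisher_enumeration(table):
    """Two-sided Fisher p by full enumeration over fixed-margin tables."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_matches_enumeration_oracle_small_tables(self, rng):
        """Implementation equals brute-force hypergeometric enumeration."""
        for _ in range(40):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0 or t.sum() > 30:
                continue
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            _, p_ref = stats.fisher_exact(t)
            p_enum = _fisher_enumeration(t)
            assert p_ref == pytest.approx(p_enum, abs=1e-10)

    def test_perfect_diagonal_significant(self):
        C = np.array([[15, 0, 0], [0, 15, 0], [0, 0, 15]])
        out = clf.fisher_pairwise(C, ["a", "h", "s"])
        enum = _fisher_enumeration([[15, 0], [0, 15]])
        assert out[("a", "h")] == pytest.approx(min(1.0, enum * 3), rel=1e-9)
        assert all(p < 0.001 for p in out.values())

    def test_no_association_table(self):
        C = np.array([[5, 5, 0], [5, 5, 0], [0, 0, 1]])
        out = clf.fisher_pairwise(C)
        assert out[(0, 1)] == 1.0

    def test_uniform_confusion_non_significant(self):
        C = np.full((3, 3), 5)
        out = clf.fisher_pairwise(C)
        assert all(p > 0.5 for p in out.values())


class TestGroupedCV:
    def test_separable_perfect(self, rng):
        X, y = _separable(rng, n_per_class=12)
        groups = np.repeat(np.arange(6), 6)
        out = clf.grouped_cross_validate(X, y, groups, "LOSO")
        assert out["mean_accuracy"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_uninformative_scores_near_chance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 3))
        y = _balanced_labels(20)
        groups = np.tile(np.arange(6), 10)
        out = clf.grouped_cross_validate(X, y, groups, "LOPO", seed=seed)
        assert 0.1 <= out["mean_accuracy"] <= 0.6

    def test_two_groups_two_folds(self, rng):
        X, y = _separable(rng, n_per_class=4)
        groups = np.tile([0, 1], 6)
        out = clf.grouped_cross_validate(X, y, groups)
        assert len(out["per_group"]) == 2

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            clf.grouped_cross_validate(rng.random((4, 2)),
                                       np.array([0, 1, 0, 1]),
                                       np.zeros(4))
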