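"""ROC AUC, cross-validated kNN/PLSDA, and bootstrap intervals."""

import itertools

import numpy as np
import pytest

from rnamotifs.classification import (
    auc_bootstrap_ci,
    knn_cv,
    plsda_cv,
    roc_auc,
)
from rnamotifs.errors import KTooLargeError, SingleClassError


def pair_count_auc(scores, labels):
    """Mann-Whitney oracle: concordant pairs + half ties over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_and_inverted(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0

    def test_partial_concordance(self):
        # positives {0.9, 0.2} vs negatives {0.1, 0.8}: 3 of 4 pairs concordant
        scores, labels = [0.9, 0.1, 0.8, 0.2], [1, 0, 0, 1]
        assert roc_auc(scores, labels) == 0.75
        assert roc_auc(scores, labels) == pair_count_auc(scores, labels)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = rng.integers(4, 20)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, size=n).astype(float)  # force ties
            assert roc_auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.4).astype(int)
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(base)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        assert roc_auc(scores, labels) == pytest.approx(
            1 - roc_auc(scores, 1 - labels))


def gaussian_blobs(n, dim=5, sep=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, size=(n, dim))
    X1 = rng.normal(sep, 1, size=(n, dim))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestKnnCv:
    def test_separated_blobs_near_perfect(self):
        X, y = gaussian_blobs(200, sep=6.0, seed=3)
        result = knn_cv(X, y, k=5, seed=0, B=100)
        assert result.auc > 0.99
        assert result.ci[0] <= result.auc <= result.ci[1]

    def test_exchangeable_classes_near_half(self):
        X, y = gaussian_blobs(300, sep=0.0, seed=4)
        result = knn_cv(X, y, k=5, seed=0, B=100)
        assert 0.42 < result.auc < 0.58

    def test_deterministic_given_seed(self):
        X, y = gaussian_blobs(50, sep=1.0, seed=5)
        r1 = knn_cv(X, y, k=3, seed=7, B=100)
        r2 = knn_cv(X, y, k=3, seed=7, B=100)
        assert r1.auc == r2.auc and r1.ci == r2.ci

    def test_k_too_large(self):
        X, y = gaussian_blobs(12, seed=6)
        with pytest.raises(KTooLargeError):
            knn_cv(X, y, k=50, seed=0)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 5))
        with pytest.raises(SingleClassError):
            knn_cv(X, np.ones(30, dtype=int), k=3)


class TestPlsdaCv:
    def test_single_signal_importance(self):
        """When the label depends only on the bonds column, that coefficient
        dominates and is positive."""
        rng = np.random.default_rng(7)
        n = 300
        X = rng.normal(0, 1, size=(n, 5))
        bonds = X[:, 4]
        y = (bonds > 0).astype(int)
        result = plsda_cv(X, y, n_components=2, seed=0, B=100)
        imps = result.importances
        assert max(imps, key=lambda k: abs(imps[k])) == "bonds"
        assert imps["bonds"] > 0
        assert result.auc > 0.95
        assert set(imps) == {"bulges", "loops", "junctions", "helices", "bonds"}

    def test_exchangeable_classes_near_half(self):
        X, y = gaussian_blobs(300, sep=0.0, seed=8)
        result = plsda_cv(X, y, n_components=2, seed=0, B=100)
        assert 0.42 < result.auc < 0.58

    def test_vip_present_and_nonnegative(self):
        X, y = gaussian_blobs(100, sep=1.0, seed=9)
        result = plsda_cv(X, y, n_components=2, seed=0, B=100)
        assert all(v >= 0 for v in result.vip.values())

    def test_component_bounds(self):
        X, y = gaussian_blobs(50, seed=10)
        with pytest.raises(ValueError):
            plsda_cv(X, y, n_components=9)


class TestAucBootstrapCi:
    def test_perfect_separation_degenerate_interval(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        assert auc_bootstrap_ci(scores, labels, B=200, seed=0) == (1.0, 1.0)

    def test_reproducible(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.5).astype(int)
        assert auc_bootstrap_ci(scores, labels, B=300, seed=1) == \
            auc_bootstrap_ci(scores, labels, B=300, seed=1)

    def test_width_near_hanley_mcneil(self):
        """Null AUC ~ 0.5, n=2000 balanced: CI width within 1.5x of the
        normal-approximation width 2 * 1.96 * sqrt(1/12 (1/n1 + 1/n0))."""
        rng = np.random.default_rng(12)
        n = 2000
        scores = rng.normal(size=n)
        labels = np.array([0, 1] * (n // 2))
        lo, hi = auc_bootstrap_ci(scores, labels, B=500, seed=2)
        se = np.sqrt((1 / 12) * (2 / (n / 2)))
        expected = 2 * 1.96 * se
        assert expected / 1.5 < (hi - lo) < expected * 1.5
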