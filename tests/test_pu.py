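"""PosOnly, SVMOnly and PSEUDO-RANDOM classifier behavior."""

import numpy as np
import pytest

from pugrn.datasets import gaussian_svm_config
from pugrn.expression import PairExample
from pugrn.pu import (
    CEstimate,
    SvmConfig,
    classify,
    estimate_c,
    fit_posonly,
    posonly_predict,
    svmonly_predict,
    train_nontraditional,
    train_pseudo_random,
)


def _blob_examples(n=60, separation=6.0, seed=0):
    """Labeled/unlabeled 2-D blobs separated along the first axis."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    s = (np.arange(n) % 2 == 0).astype(int)
    X[s == 1, 0] += separation
    return [
        PairExample(f"a{i}", f"b{i}", X[i], y=int(s[i]), s=int(s[i])) for i in range(n)
    ]


class TestTrainNontraditional:
    def test_separable_blobs_score_by_side(self):
        examples = _blob_examples()
        clf = train_nontraditional(examples, gaussian_svm_config(), seed=0)
        assert clf.score(np.array([6.0, 0.0])) > 0.5
        assert clf.score(np.array([0.0, 0.0])) < 0.5

    def test_constant_features_score_near_base_rate(self):
        examples = [
            PairExample(f"a{i}", f"b{i}", np.zeros(2), y=i % 4 == 0, s=int(i % 4 == 0))
            for i in range(40)
        ]
        clf = train_nontraditional(examples, SvmConfig(C=1.0, gamma=1.0), seed=0)
        assert abs(clf.score(np.zeros(2)) - 0.25) < 0.15

    def test_deterministic_given_seed(self):
        examples = _blob_examples()
        probe = np.linspace(-1, 7, 10)[:, None] * np.array([1.0, 0.0])
        a = train_nontraditional(examples, gaussian_svm_config(), seed=3).score_many(probe)
        b = train_nontraditional(examples, gaussian_svm_config(), seed=3).score_many(probe)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        examples = [
            PairExample(f"a{i}", f"b{i}", np.zeros(2), y=1, s=1) for i in range(5)
        ]
        with pytest.raises(ValueError, match="at least one"):
            train_nontraditional(examples, SvmConfig(), seed=0)


class TestEstimateC:
    class _Fixed:
        def __init__(self, scores):
            self._scores = np.asarray(scores, float)

        def score_many(self, X):
            return self._scores[: len(X)]

    def _positives(self, n):
        return [PairExample(f"a{i}", f"b{i}", np.zeros(1), y=1, s=1) for i in range(n)]

    def test_perfect_scores_give_c_one(self):
        assert estimate_c(self._Fixed([1.0, 1.0]), self._positives(2)).c == 1.0

    def test_arithmetic_mean(self):
        assert estimate_c(self._Fixed([0.4, 0.6]), self._positives(2)).c == pytest.approx(0.5)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_c(self._Fixed([]), [])

    def test_unlabeled_validation_rejected(self):
        bad = [PairExample("a", "b", np.zeros(1), y=1, s=0)]
        with pytest.raises(ValueError, match="labeled positives"):
            estimate_c(self._Fixed([0.5]), bad)

    def test_clipping_bounds(self):
        assert CEstimate(0.0).c > 0
        assert CEstimate(1.7).c == 1.0


class TestPredictions:
    class _Fixed:
        def __init__(self, score):
            self._score = score

        def score(self, x):
            return self._score

        def score_many(self, X):
            return np.full(len(X), self._score)

    def test_posonly_divides_by_c(self):
        assert posonly_predict(self._Fixed(0.3), CEstimate(0.5), np.zeros(1)) == pytest.approx(0.6)

    def test_posonly_clips_at_one(self):
        assert posonly_predict(self._Fixed(0.9), CEstimate(0.5), np.zeros(1)) == 1.0

    def test_c_one_reduces_to_svmonly(self):
        clf = self._Fixed(0.42)
        x = np.zeros(1)
        assert posonly_predict(clf, CEstimate(1.0), x) == svmonly_predict(clf, x)

    def test_posonly_preserves_svmonly_ranking(self):
        examples = _blob_examples()
        clf = train_nontraditional(examples, gaussian_svm_config(), seed=0)
        probe = np.random.default_rng(1).normal(size=(30, 2)) * 3
        raw = clf.score_many(probe)
        adjusted = raw / 0.6  # any positive constant
        assert np.array_equal(np.argsort(raw), np.argsort(adjusted))


class TestClassify:
    @pytest.mark.parametrize(
        "p, expected", [(0.51, 1), (0.5, 0), (0.0, 0), (1.0, 1)]
    )
    def test_strict_threshold(self, p, expected):
        assert classify(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.5)


class TestTrainPseudoRandom:
    def test_chain_training_set_sizes(self, chain):
        from pugrn.expression import build_pair_dataset
        from pugrn.network import LabelPartition, all_ordered_pairs, pseudo_random_negatives

        net, expr = chain
        universe = frozenset(all_ordered_pairs(net.genes))
        part = LabelPartition(net.genes, net.edges, frozenset(), universe - net.edges)
        examples = build_pair_dataset(expr, part)
        negs = pseudo_random_negatives(net, net.genes, random_fraction=0.0)
        assert len(negs) == 4
        clf = train_pseudo_random(examples, negs, SvmConfig(C=10, gamma=0.5), seed=0)
        # trains on 2 positives and 4 negatives; fitted support reflects both classes
        assert clf._model.n_support_.sum() <= 6

    def test_empty_negatives_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_pseudo_random(_blob_examples(), frozenset(), SvmConfig(), seed=0)

    def test_negatives_missing_from_examples_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            train_pseudo_random(
                _blob_examples(), {("zz", "yy")}, SvmConfig(), seed=0
            )

    def test_all_unlabeled_as_negatives_matches_svmonly_setup(self):
        examples = _blob_examples()
        negs = {ex.pair for ex in examples if ex.s == 0}
        a = train_pseudo_random(examples, negs, gaussian_svm_config(), seed=1)
        b = train_nontraditional(examples, gaussian_svm_config(), seed=1)
        probe = np.random.default_rng(2).normal(size=(20, 2)) * 3
        assert np.allclose(a.score_many(probe), b.score_many(probe))


class TestFitPosonly:
    def test_returns_c_in_unit_interval(self):
        clf, c = fit_posonly(_blob_examples(n=100), gaussian_svm_config(), seed=0)
        assert 0 < c.c <= 1

    def test_deterministic(self):
        probe = np.random.default_rng(3).normal(size=(10, 2))
        r1 = fit_posonly(_blob_examples(n=100), gaussian_svm_config(), seed=5)
        r2 = fit_posonly(_blob_examples(n=100), gaussian_svm_config(), seed=5)
        assert r1[1].c == r2[1].c
        assert np.array_equal(r1[0].score_many(probe), r2[0].score_many(probe))

    def test_fallback_warns_when_holdout_has_no_positives(self):
        # one labeled positive among many unlabeled: the 20% holdout usually
        # misses it, triggering the resubstitution fallback
        rng = np.random.default_rng(0)
        examples = [
            PairExample(f"a{i}", f"b{i}", rng.normal(size=2), y=int(i == 3), s=int(i == 3))
            for i in range(10)
        ]
        with pytest.warns(UserWarning, match="holdout"):
            fit_posonly(examples, SvmConfig(C=1, gamma=0.5), seed=1)
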