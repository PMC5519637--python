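"""One-vs-one training, vote counting and deterministic tie-breaking."""

import numpy as np
import pytest

from wavebeat import ovo_svm
from wavebeat.errors import PredictionError, TrainingError
from wavebeat.ovo_svm import (BinaryHyperplane, OvoModel, SvmConfig,
                              count_votes, predict, train_ovo)


def _blobs(n_classes=6, per_class=30, sep=30.0, dim=4, seed=7):
    """Well-separated Gaussian blobs, one per class."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_classes, dim)) * sep
    X = np.vstack([
        centers[i] + rng.normal(size=(per_class, dim))
        for i in range(n_classes)
    ])
    y = np.repeat([chr(ord("A") + i) for i in range(n_classes)], per_class)
    return X, y


class _FixedDecision:
    """Stub binary solver with a constant signed score."""

    def __init__(self, score):
        self.score = float(score)

    def decision_function(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.score)


def constructed_model(classes, pair_scores):
    """Build a model whose pairwise outcomes are fixed by ``pair_scores``.

    ``pair_scores[(a, b)]`` (a < b) is the signed score: positive means
    the pair's hyperplane picks b, negative picks a.
    """
    hyperplanes = [
        BinaryHyperplane(class_pair=pair, svc=_FixedDecision(score))
        for pair, score in sorted(pair_scores.items())
    ]
    return OvoModel(classes=tuple(classes), hyperplanes=hyperplanes,
                    n_features=1)


def oracle_predict(classes, pair_scores):
    """Independent enumeration oracle for the majority-vote rule."""
    votes = {c: 0 for c in classes}
    for (a, b), s in pair_scores.items():
        votes[b if s > 0 else a] += 1
    top = max(votes.values())
    tied = [c for c in classes if votes[c] == top]
    if len(tied) == 1:
        return tied[0]
    if len(tied) == 2:
        a, b = sorted(tied)
        return b if pair_scores[(a, b)] > 0 else a
    margins = {}
    for c in tied:
        total = 0.0
        for (a, b), s in pair_scores.items():
            if c == b:
                total += s
            elif c == a:
                total -= s
        margins[c] = total
    best = max(margins.values())
    for c in classes:  # earliest class in model order wins exact ties
        if c in tied and margins[c] == best:
            return c


def random_pair_scores(classes, rng):
    scores = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            s = 0.0
            while s == 0.0:
                s = rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 2.0)
            scores[(a, b)] = float(s)
    return scores


class TestTraining:
    def test_six_classes_give_15_hyperplanes(self):
        X, y = _blobs(6)
        model = train_ovo(X, y)
        assert len(model.hyperplanes) == 15
        pairs = {h.class_pair for h in model.hyperplanes}
        assert len(pairs) == 15  # one per unordered pair

    def test_two_classes_give_one_hyperplane(self):
        X, y = _blobs(2)
        assert len(train_ovo(X, y).hyperplanes) == 1

    def test_separable_blobs_classified_perfectly(self):
        X, y = _blobs(6, sep=30.0)
        model = train_ovo(X, y)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_missing_declared_class_named_in_error(self):
        X, y = _blobs(3)
        with pytest.raises(TrainingError, match="Z"):
            train_ovo(X, y, classes=["A", "B", "C", "Z"])

    def test_single_class_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(TrainingError):
            train_ovo(X, ["N"] * 5)

    def test_standardization_makes_training_affine_invariant(self):
        X, y = _blobs(4, seed=9)
        scale = np.array([100.0, 0.01, 3.0, 1e4])
        shift = np.array([5.0, -3.0, 0.0, 1e3])
        m1 = train_ovo(X, y, SvmConfig(standardize=True))
        m2 = train_ovo(X * scale + shift, y, SvmConfig(standardize=True))
        probe = X[::3]
        p1 = predict(m1, probe)
        p2 = predict(m2, probe * scale + shift)
        assert np.array_equal(p1, p2)


class TestVoting:
    def test_vote_conservation(self):
        X, y = _blobs(5, sep=2.0)  # overlapping blobs: contested votes
        model = train_ovo(X, y)
        n = model.n_classes
        for x in X[::7]:
            tally = count_votes(model, x)
            assert sum(tally.values()) == n * (n - 1) // 2
            assert max(tally.values()) <= n - 1

    def test_two_class_tally_is_one_zero(self):
        X, y = _blobs(2)
        model = train_ovo(X, y)
        tally = count_votes(model, X[0])
        assert sorted(tally.values()) == [0, 1]

    def test_tally_matches_enumeration_on_constructed_model(self, rng):
        classes = list("ABCDEF")
        scores = random_pair_scores(classes, rng)
        model = constructed_model(classes, scores)
        tally = count_votes(model, np.zeros(1))
        expected = {c: 0 for c in classes}
        for (a, b), s in scores.items():
            expected[b if s > 0 else a] += 1
        assert tally == expected

    def test_prediction_dimension_checked(self):
        X, y = _blobs(3)
        model = train_ovo(X, y)
        with pytest.raises(PredictionError):
            predict(model, np.ones(X.shape[1] + 1))


class TestTieBreaking:
    def test_clear_winner_takes_the_sample(self):
        classes = list("ABC")
        scores = {("A", "B"): -1.0, ("A", "C"): -1.0, ("B", "C"): 1.0}
        model = constructed_model(classes, scores)  # A beats B and C
        assert predict(model, np.zeros(1)) == "A"

    def test_two_way_tie_resolved_by_direct_hyperplane(self):
        # n=4: A and B tie at 2 votes; their own hyperplane picked B
        classes = list("ABCD")
        scores = {("A", "B"): 0.5, ("A", "C"): -1.0, ("A", "D"): -1.0,
                  ("B", "C"): -1.0, ("B", "D"): 1.0, ("C", "D"): -1.0}
        model = constructed_model(classes, scores)
        votes = count_votes(model, np.zeros(1))
        assert votes["A"] == votes["B"] == 2
        assert predict(model, np.zeros(1)) == "B"

    def test_three_way_tie_resolved_by_signed_margin(self):
        # cyclic A>B, B>C, C>A: all tie at 1 vote
        classes = list("ABC")
        scores = {("A", "B"): -0.1, ("B", "C"): -2.0, ("A", "C"): 0.5}
        model = constructed_model(classes, scores)
        votes = count_votes(model, np.zeros(1))
        assert set(votes.values()) == {1}
        # margins: A = 0.1-0.5 = -0.4; B = -0.1+2.0 = 1.9; C = -2.0+0.5 = -1.5
        assert predict(model, np.zeros(1)) == "B"

    def test_repeated_calls_agree_exactly(self):
        X, y = _blobs(4, sep=1.0)
        model = train_ovo(X, y)
        p1 = predict(model, X)
        p2 = predict(model, X)
        assert np.array_equal(p1, p2)


class TestRandomizedAgainstOracle:
    def test_predict_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 7))
            classes = [chr(ord("A") + i) for i in range(n)]
            scores = random_pair_scores(classes, rng)
            model = constructed_model(classes, scores)
            assert predict(model, np.zeros(1)) == oracle_predict(classes, scores)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = _blobs(3)
        model = train_ovo(X, y)
        path = ovo_svm.save_model(model, tmp_path / "model.joblib")
        back = ovo_svm.load_model(path)
        assert back.classes == model.classes
        assert np.array_equal(predict(back, X), predict(model, X))
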