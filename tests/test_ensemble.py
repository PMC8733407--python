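"""EasyEnsemble / RS-EasyEnsemble: partitioning, fitting, voting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adiag.ensemble import (BaseClassifierRecord, RSEnsembleModel,
                            easy_ensemble_fit, make_adaboost,
                            partition_majority, rs_easy_ensemble_fit,
                            rs_predict)
from adiag.errors import InvalidTrainingDataError

from conftest import cohort_from_arrays, separable_cohort


class TestPartitionMajority:
    def test_exact_division(self):
        subsets = partition_majority(np.arange(650), 10, seed=0)
        assert len(subsets) == 65
        assert all(len(s) == 10 for s in subsets)
        assert len(np.unique(np.concatenate(subsets))) == 650

    def test_remainder_left_unused(self):
        subsets = partition_majority(np.arange(657), 10, seed=1)
        assert len(subsets) == 65
        assert len(np.concatenate(subsets)) == 650

    @given(st.integers(1, 40), st.integers(1, 8), st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_disjointness_property(self, n_mult, p_size, seed):
        n = p_size * n_mult + seed % p_size
        subsets = partition_majority(np.arange(100, 100 + n), p_size, seed)
        flat = np.concatenate(subsets)
        assert len(flat) == len(set(flat))          # pairwise disjoint
        assert all(len(s) == p_size for s in subsets)

    def test_insufficient_majority(self):
        with pytest.raises(InvalidTrainingDataError):
            partition_majority(np.arange(5), 10, seed=0)


class _ForcedVote:
    """Stub classifier that always answers a fixed label."""

    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


def _forced_model(votes, n_features=3, selected=None):
    bases = [BaseClassifierRecord(_ForcedVote(v), np.arange(n_features), i,
                                  selected=True if selected is None else selected[i])
             for i, v in enumerate(votes)]
    return RSEnsembleModel(bases, n_features, 1.0, 0)


class TestVoteArithmetic:
    def test_rounded_mean_vote_of_selected_half(self):
        # M = 10, half selected: 3 of 5 positive votes -> (2/10)*3 = 0.6 -> 1
        sel = [True] * 5 + [False] * 5
        model = _forced_model([1, 1, 1, 0, 0] + [1] * 5, selected=sel)
        assert rs_predict(model, np.zeros((4, 3)))[0] == 1
        # 2 of 5 positive -> 0.4 -> 0
        model = _forced_model([1, 1, 0, 0, 0] + [1] * 5, selected=sel)
        assert rs_predict(model, np.zeros((1, 3)))[0] == 0

    def test_half_up_tie_goes_positive(self):
        # M = 8, 4 selected, 2 positive votes -> exactly 0.5 -> 1
        sel = [True] * 4 + [False] * 4
        model = _forced_model([1, 1, 0, 0] + [0] * 4, selected=sel)
        assert rs_predict(model, np.zeros((1, 3)))[0] == 1

    def test_monotone_in_votes(self):
        # adding a positive vote never flips a positive prediction negative
        for k in range(7):
            votes = [1] * k + [0] * (6 - k)
            pred = rs_predict(_forced_model(votes), np.zeros((1, 3)))[0]
            if k < 6:
                more = rs_predict(_forced_model([1] * (k + 1) + [0] * (5 - k)),
                                  np.zeros((1, 3)))[0]
                assert more >= pred

    def test_shape_mismatch(self):
        model = _forced_model([1, 0])
        with pytest.raises(ValueError, match="feature columns"):
            rs_predict(model, np.zeros((2, 5)))


class TestEasyEnsemble:
    def test_balanced_bases_and_auto_count(self, small_separable):
        model = easy_ensemble_fit(small_separable, boosting_rounds=5, seed=0)
        n_pos = (small_separable.labels == 1).sum()
        assert model.M == (small_separable.labels == 0).sum() // n_pos
        for base in model.bases:
            yb = small_separable.labels[base.train_indices]
            assert (yb == 1).sum() == n_pos and (yb == 0).sum() == n_pos
            assert base.selected

    def test_perfect_recall_on_separable_data(self, small_separable):
        model = easy_ensemble_fit(small_separable, boosting_rounds=10, seed=1)
        pred = model.predict(small_separable.X)
        assert (pred[small_separable.labels == 1] == 1).all()

    def test_seeded_determinism(self, small_separable):
        Xt = np.random.default_rng(99).normal(size=(20, small_separable.d))
        p1 = easy_ensemble_fit(small_separable, boosting_rounds=5, seed=4).predict(Xt)
        p2 = easy_ensemble_fit(small_separable, boosting_rounds=5, seed=4).predict(Xt)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        c = cohort_from_arrays(np.random.default_rng(0).normal(size=(20, 2)),
                               np.zeros(20, int))
        with pytest.raises(InvalidTrainingDataError):
            easy_ensemble_fit(c)


class TestRSEasyEnsemble:
    def test_subspace_sizes_and_selected_count(self, small_separable):
        d = small_separable.d
        model = rs_easy_ensemble_fit(small_separable, M=10,
                                     subspace_fraction=0.5,
                                     boosting_rounds=5, seed=2)
        assert all(len(b.subspace) == round(0.5 * d) for b in model.bases)
        assert all(len(set(b.subspace)) == len(b.subspace) for b in model.bases)
        assert sum(b.selected for b in model.bases) == 5
        # bases ranked by held-out recall then accuracy
        scores = [b.validation_score for b in model.bases]
        worst_kept = min(s for b, s in zip(model.bases, scores) if b.selected)
        best_dropped = max(s for b, s in zip(model.bases, scores) if not b.selected)
        assert worst_kept >= best_dropped

    def test_odd_m_rejected(self, small_separable):
        with pytest.raises(ValueError, match="even"):
            rs_easy_ensemble_fit(small_separable, M=3)

    def test_empty_subspace_rejected(self, small_separable):
        with pytest.raises(ValueError):
            rs_easy_ensemble_fit(small_separable, M=2, subspace_fraction=0.01,
                                 boosting_rounds=2)

    def test_reduces_to_easy_ensemble(self, small_separable):
        n_pos = (small_separable.labels == 1).sum()
        T = (small_separable.labels == 0).sum() // n_pos
        Xt = np.random.default_rng(7).normal(size=(50, small_separable.d))
        ee = easy_ensemble_fit(small_separable, T_count=T, boosting_rounds=5,
                               seed=13)
        rs = rs_easy_ensemble_fit(small_separable, M=T, subspace_fraction=1.0,
                                  boosting_rounds=5, seed=13,
                                  select_best_half=False)
        assert np.array_equal(ee.predict(Xt), rs.predict(Xt))

    def test_balanced_bases_after_validation_split(self, small_separable):
        model = rs_easy_ensemble_fit(small_separable, M=6, boosting_rounds=3,
                                     seed=5)
        y = small_separable.labels
        for base in model.bases:
            yb = y[base.train_indices]
            assert (yb == 1).sum() == (yb == 0).sum() == model.meta["P"]


class TestAgainstStepwiseBoostingOracle:
    """Base committees agree with an exhaustively verified stump-boosting
    reference on a tiny separable cohort."""

    @staticmethod
    def _oracle_adaboost(X, y, rounds):
        # discrete AdaBoost with exhaustive decision stumps, run step by step
        n = len(y)
        w = np.full(n, 1 / n)
        stumps, alphas = [], []
        for _ in range(rounds):
            best = None
            for j in range(X.shape[1]):
                order = np.argsort(X[:, j])
                xs = X[order, j]
                cuts = np.concatenate([[-np.inf], (xs[:-1] + xs[1:]) / 2])
                for c in np.unique(cuts):
                    for sign in (1, -1):
                        pred = np.where((X[:, j] > c), 1, 0)
                        if sign < 0:
                            pred = 1 - pred
                        err = w[pred != y].sum()
                        if best is None or err < best[0] - 1e-12:
                            best = (err, j, c, sign)
            err, j, c, sign = best
            err = min(max(err, 1e-10), 1 - 1e-10)
            alpha = 0.5 * np.log((1 - err) / err)
            pred = np.where(X[:, j] > c, 1, 0)
            if sign < 0:
                pred = 1 - pred
            w *= np.exp(alpha * np.where(pred != y, 1, -1))
            w /= w.sum()
            stumps.append((j, c, sign))
            alphas.append(alpha)
        def predict(Xq):
            score = np.zeros(len(Xq))
            for (j, c, sign), a in zip(stumps, alphas):
                pred = np.where(Xq[:, j] > c, 1, 0)
                if sign < 0:
                    pred = 1 - pred
                score += a * np.where(pred == 1, 1, -1)
            return (score > 0).astype(int)
        return predict

    def test_training_predictions_match(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(4, 1, size=(10, 3)),
                       rng.normal(0, 1, size=(10, 3))])
        y = np.array([1] * 10 + [0] * 10)
        oracle = self._oracle_adaboost(X, y, rounds=5)
        clf = make_adaboost(boosting_rounds=5, random_state=0).fit(X, y)
        assert np.array_equal(clf.predict(X), oracle(X))
        assert np.array_equal(oracle(X), y)
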