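"""EasyEnsemble and its random-subspace variant (RS-EasyEnsemble).

EasyEnsemble attacks severe class imbalance by undersampling *without*
throwing data away: the majority class N is partitioned into disjoint subsets
T_1..T_T each the size of the minority class P, and one AdaBoost committee
H_i is trained on every balanced set T_i ∪ P. RS-EasyEnsemble adds two
ingredients aimed at base-classifier diversity and quality:

* each base classifier sees only a random feature subspace S_i (default half
  of the features), drawn independently per base;
* after training M bases, only the best-scoring half is retained, and the
  ensemble output is the rounded mean vote of the retained half,
  H(x) = round((2/M) * sum of the M/2 selected H_i(x)), with half-up
  rounding so that a tied vote is resolved toward the positive (AD) class.

The selection score is recall on a held-out stratified validation split —
the design objective is to miss as few true cases as possible — with
accuracy and then base index as tie-breakers.

All randomness is driven by a single integer seed through
``numpy.random.default_rng``; identical (data, config, seed) give identical
models and predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .cohort import CohortTable
from .errors import InvalidTrainingDataError

__all__ = [
    "BaseClassifierRecord",
    "RSEnsembleModel",
    "partition_majority",
    "easy_ensemble_fit",
    "rs_easy_ensemble_fit",
    "rs_predict",
    "make_adaboost",
]

DEFAULT_BOOSTING_ROUNDS = 50
DEFAULT_MAX_SUBSETS = 50


@dataclass
class BaseClassifierRecord:
    """One trained base committee with its feature subspace and provenance."""

    classifier: object
    subspace: np.ndarray          # ordered feature-column indices
    majority_subset_id: int
    validation_score: tuple = ()  # (recall, accuracy) on the validation split
    selected: bool = True
    train_indices: np.ndarray | None = None  # cohort row indices used to fit

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.classifier.predict(X[:, self.subspace]), dtype=int)


@dataclass
class RSEnsembleModel:
    """An ensemble of M base committees; prediction is the rounded mean vote
    of the selected bases (see :func:`rs_predict`)."""

    bases: list[BaseClassifierRecord]
    n_features: int
    subspace_fraction: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.bases)

    @property
    def selected_bases(self) -> list[BaseClassifierRecord]:
        return [b for b in self.bases if b.selected]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return rs_predict(self, X)


def partition_majority(n_indices: np.ndarray, p_size: int, seed: int | np.random.Generator
                       ) -> list[np.ndarray]:
    """Partition majority-class indices into floor(|N|/p_size) disjoint
    subsets of exactly ``p_size`` via a seeded shuffle; the |N| mod p_size
    leftover indices are unused."""
    n_indices = np.asarray(n_indices)
    if p_size < 1:
        raise ValueError("p_size must be >= 1")
    if len(n_indices) < p_size:
        raise InvalidTrainingDataError(
            f"majority class ({len(n_indices)}) smaller than minority ({p_size})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = rng.permutation(n_indices)
    n_subsets = len(n_indices) // p_size
    return [shuffled[i * p_size:(i + 1) * p_size] for i in range(n_subsets)]


def make_adaboost(boosting_rounds: int, random_state: int) -> AdaBoostClassifier:
    """AdaBoost of depth-1 decision stumps (the classic weak learner)."""
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1, random_state=random_state),
        n_estimators=boosting_rounds,
        random_state=random_state,
    )


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise InvalidTrainingDataError("training cohort contains a single class")


def _fit_bases(X, y, subsets, p_idx, M, subspace_fraction, boosting_rounds, rng,
               abs_idx=None):
    d = X.shape[1]
    k = int(round(subspace_fraction * d))
    if k < 1:
        raise ValueError("subspace_fraction * n_features must be >= 1")
    if abs_idx is None:
        abs_idx = np.arange(len(y))
    bases = []
    for i in range(M):
        if subspace_fraction >= 1.0:
            subspace = np.arange(d)
        else:
            subspace = np.sort(rng.choice(d, size=k, replace=False))
        t_idx = subsets[i % len(subsets)]
        train_idx = np.concatenate([p_idx, t_idx])
        rs = int(rng.integers(0, 2**31 - 1))
        clf = make_adaboost(boosting_rounds, rs)
        clf.fit(X[np.ix_(train_idx, subspace)], y[train_idx])
        bases.append(BaseClassifierRecord(clf, subspace, i,
                                          train_indices=abs_idx[train_idx]))
    return bases


def easy_ensemble_fit(cohort: CohortTable, T_count: int | str = "auto",
                      boosting_rounds: int = DEFAULT_BOOSTING_ROUNDS,
                      seed: int = 0,
                      max_subsets: int = DEFAULT_MAX_SUBSETS) -> RSEnsembleModel:
    """Plain EasyEnsemble: full feature space, every base retained.

    ``T_count='auto'`` uses floor(|N|/|P|) balanced subsets, capped at
    ``max_subsets`` to bound runtime. Prediction is the rounded mean vote
    over all bases (majority vote, ties to the positive class).
    """
    X, y = cohort.X, cohort.labels
    _check_two_classes(y)
    rng = np.random.default_rng(seed)
    p_idx = np.flatnonzero(y == 1)
    n_idx = np.flatnonzero(y == 0)
    subsets = partition_majority(n_idx, len(p_idx), rng)
    if T_count == "auto":
        T_count = min(len(subsets), max_subsets)
    elif T_count < 1:
        raise ValueError("T_count must be >= 1")
    bases = _fit_bases(X, y, subsets, p_idx, int(T_count), 1.0, boosting_rounds, rng)
    return RSEnsembleModel(bases, X.shape[1], 1.0, seed,
                           meta={"method": "easyensemble", "P": len(p_idx),
                                 "N": len(n_idx), "T": len(subsets),
                                 "boosting_rounds": boosting_rounds})


def rs_easy_ensemble_fit(cohort: CohortTable, M: int = 20,
                         subspace_fraction: float = 0.5,
                         boosting_rounds: int = DEFAULT_BOOSTING_ROUNDS,
                         seed: int = 0, selection_split: float = 0.25,
                         select_best_half: bool = True) -> RSEnsembleModel:
    """RS-EasyEnsemble: M bases on random feature subspaces, best half kept.

    A stratified ``selection_split`` fraction of the cohort is held out to
    score the M bases (recall, then accuracy, then base index); the top M/2
    are marked selected. With ``select_best_half=False`` no validation split
    is made and every base is retained — combined with
    ``subspace_fraction=1`` this reduces exactly to plain EasyEnsemble.
    """
    X, y = cohort.X, cohort.labels
    _check_two_classes(y)
    if select_best_half and (M < 2 or M % 2 != 0):
        raise ValueError(f"M must be even and >= 2, got {M}")
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0.0 < subspace_fraction <= 1.0:
        raise ValueError("subspace_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    if select_best_half:
        idx_fit, idx_val = train_test_split(
            np.arange(len(y)), test_size=selection_split,
            stratify=cohort.stratum,
            random_state=int(rng.integers(0, 2**31 - 1)))
        _check_two_classes(y[idx_fit])
    else:
        idx_fit, idx_val = np.arange(len(y)), np.array([], dtype=int)

    Xf, yf = X[idx_fit], y[idx_fit]
    p_idx = np.flatnonzero(yf == 1)
    n_idx = np.flatnonzero(yf == 0)
    subsets = partition_majority(n_idx, len(p_idx), rng)
    bases = _fit_bases(Xf, yf, subsets, p_idx, M, subspace_fraction,
                       boosting_rounds, rng, abs_idx=np.asarray(idx_fit))

    if select_best_half:
        Xv, yv = X[idx_val], y[idx_val]
        n_pos = max(int((yv == 1).sum()), 1)
        for b in bases:
            pred = b.predict(Xv)
            rec = float((pred[yv == 1] == 1).sum()) / n_pos
            acc = float((pred == yv).mean())
            b.validation_score = (rec, acc)
        ranked = sorted(range(M),
                        key=lambda i: (-bases[i].validation_score[0],
                                       -bases[i].validation_score[1], i))
        keep = set(ranked[: M // 2])
        for i, b in enumerate(bases):
            b.selected = i in keep

    return RSEnsembleModel(bases, X.shape[1], subspace_fraction, seed,
                           meta={"method": "rs-easyensemble", "M": M,
                                 "P": len(p_idx), "N": len(n_idx),
                                 "T": len(subsets),
                                 "boosting_rounds": boosting_rounds,
                                 "selection": select_best_half,
                                 "selection_split": selection_split})


def rs_predict(model: RSEnsembleModel, X: np.ndarray) -> np.ndarray:
    """Rounded mean vote of the selected bases.

    For a full M-base ensemble with M/2 selected this is exactly
    round((2/M) * sum of selected votes); rounding is half-up, computed in
    integer arithmetic (2 * votes >= n_selected), so a tie goes to class 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got "
            f"{X.shape[1] if X.ndim == 2 else X.shape}")
    selected = model.selected_bases
    votes = np.zeros(len(X), dtype=int)
    for b in selected:
        votes += b.predict(X)
    return (2 * votes >= len(selected)).astype(int)
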