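"""The four comparison classifiers behind one fit/predict contract.

These are the models the ensemble is compared against, trained on the raw
imbalanced cohort exactly as the comparison intends — no resampling or class
weighting:

* ``lda`` — linear discriminant analysis; per-class linear scores, argmax.
* ``bp``  — a single-hidden-layer error-back-propagation network minimising
  mean squared error with a sigmoid output thresholded at 0.5. Implemented
  directly in numpy: the squared-error objective and recorded loss trace are
  part of the contract.
* ``dt``  — a random forest (the decision-tree family realised as a forest
  with mode-vote aggregation).
* ``svm`` — RBF-kernel support vector machine with the study's stated
  hyperparameters as defaults: C = 0.125, gamma = 0.0078125, degree = 3.

Features are standardized (train-set mean/SD) for LDA, BP and SVM; trees get
raw values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import CohortTable
from .errors import DivergenceError, InvalidTrainingDataError

__all__ = [
    "SVM_DEFAULTS",
    "lda_fit", "lda_predict",
    "bp_fit", "bp_predict", "BPNetwork",
    "dt_fit", "dt_predict",
    "svm_fit", "svm_predict",
]

log = logging.getLogger(__name__)

#: Stated support-vector-machine hyperparameters.
SVM_DEFAULTS = {"C": 0.125, "kernel": "rbf", "degree": 3, "gamma": 0.0078125}


def _check_cohort(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    X, y = cohort.X, cohort.labels
    if len(np.unique(y)) < 2:
        raise InvalidTrainingDataError("training cohort contains a single class")
    return X, y


# ---------------------------------------------------------------------------
# Linear discriminant analysis

def lda_fit(cohort: CohortTable):
    X, y = _check_cohort(cohort)
    pipe = Pipeline([("scale", StandardScaler()),
                     ("lda", LinearDiscriminantAnalysis(solver="lsqr"))])
    try:
        pipe.fit(X, y)
    except np.linalg.LinAlgError:
        log.warning("singular within-class scatter; refitting with shrinkage")
        pipe = Pipeline([("scale", StandardScaler()),
                         ("lda", LinearDiscriminantAnalysis(solver="lsqr",
                                                            shrinkage="auto"))])
        pipe.fit(X, y)
    return pipe


def lda_predict(model, X: np.ndarray) -> np.ndarray:
    # strict > so an exact tie between the class scores resolves to class 0
    return (model.decision_function(np.asarray(X, dtype=float)) > 0).astype(int)


# ---------------------------------------------------------------------------
# Back-propagation network

@dataclass
class BPNetwork:
    """Single-hidden-layer sigmoid network trained by full-batch gradient
    descent on the mean squared error; loss per epoch is recorded."""

    hidden: int = 16
    epochs: int = 500
    learning_rate: float = 0.5
    seed: int = 0
    loss_trace: list = field(default_factory=list)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BPNetwork":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        self._mu = X.mean(axis=0)
        self._sigma = X.std(axis=0)
        self._sigma[self._sigma == 0] = 1.0
        Z = (X - self._mu) / self._sigma

        rng = np.random.default_rng(self.seed)
        d = Z.shape[1]
        self.W1 = rng.normal(0, 1.0 / np.sqrt(d), size=(d, self.hidden))
        self.b1 = np.zeros(self.hidden)
        self.W2 = rng.normal(0, 1.0 / np.sqrt(self.hidden), size=(self.hidden, 1))
        self.b2 = np.zeros(1)

        n = len(Z)
        self.loss_trace = []
        for epoch in range(self.epochs):
            H = _sigmoid(Z @ self.W1 + self.b1)
            out = _sigmoid(H @ self.W2 + self.b2)
            err = out - y
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            self.loss_trace.append(loss)
            # backprop through sigmoid output and hidden layer
            delta_out = 2.0 * err * out * (1 - out) / n
            grad_W2 = H.T @ delta_out
            grad_b2 = delta_out.sum(axis=0)
            delta_h = (delta_out @ self.W2.T) * H * (1 - H)
            grad_W1 = Z.T @ delta_h
            grad_b1 = delta_h.sum(axis=0)
            self.W2 -= self.learning_rate * grad_W2
            self.b2 -= self.learning_rate * grad_b2
            self.W1 -= self.learning_rate * grad_W1
            self.b1 -= self.learning_rate * grad_b1
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self._mu) / self._sigma
        H = _sigmoid(Z @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bp_fit(cohort: CohortTable, epochs: int = 500, learning_rate: float = 0.5,
           seed: int = 0, hidden: int = 16) -> BPNetwork:
    X, y = _check_cohort(cohort)
    return BPNetwork(hidden=hidden, epochs=epochs,
                     learning_rate=learning_rate, seed=seed).fit(X, y)


def bp_predict(model: BPNetwork, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# Random forest ("decision tree" family) and support vector machine

def dt_fit(cohort: CohortTable, n_trees: int = 100, seed: int = 0):
    X, y = _check_cohort(cohort)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    return forest.fit(X, y)


def dt_predict(model, X: np.ndarray) -> np.ndarray:
    return np.asarray(model.predict(np.asarray(X, dtype=float)), dtype=int)


def svm_fit(cohort: CohortTable, **overrides):
    X, y = _check_cohort(cohort)
    params = {**SVM_DEFAULTS, **overrides}
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(**params))])
    return pipe.fit(X, y)


def svm_predict(model, X: np.ndarray) -> np.ndarray:
    return np.asarray(model.predict(np.asarray(X, dtype=float)), dtype=int)
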