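"""Stratified confusion accounting and the study's four headline metrics.

Because chest pain (thoracalgia) dominates the differential diagnosis, false
positives among controls are reported separately for controls *with* and
*without* chest pain. The test set therefore splits into six cells:

    TP / FN        among true AD cases,
    TN_t / FP_t    among non-AD patients with thoracalgia,
    TN_nt / FP_nt  among non-AD patients without thoracalgia,

and the metrics, all on the percent scale, are

    accuracy  A     = (TP + TN) / total * 100         (TN = TN_t + TN_nt)
    recall    R     = TP / (TP + FN) * 100            (the priority metric)
    ER_t            = FP_t / (TN_t + FP_t) * 100
    ER_nt           = FP_nt / (TN_nt + FP_nt) * 100

A metric whose denominator is empty is *not applicable* and reported as NaN
(rendered "n/a"), never as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import baselines, ensemble
from .cohort import STRATUM_AD, STRATUM_NONAD_NT, STRATUM_NONAD_T, CohortTable

__all__ = [
    "StratifiedConfusion",
    "tally",
    "accuracy",
    "recall",
    "error_rate_t",
    "error_rate_nt",
    "metrics_row",
    "split_cohort",
    "fit_method",
    "predict_method",
    "compare_models",
    "ALL_METHODS",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratifiedConfusion:
    tp: int
    fn: int
    tn_t: int
    fp_t: int
    tn_nt: int
    fp_nt: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn_t, self.fp_t, self.tn_nt, self.fp_nt) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def tn(self) -> int:
        return self.tn_t + self.tn_nt

    @property
    def fp(self) -> int:
        return self.fp_t + self.fp_nt

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def tally(predictions: np.ndarray, labels: np.ndarray,
          stratum: np.ndarray) -> StratifiedConfusion:
    """Count the six stratified confusion cells."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    strat = np.asarray(stratum, dtype=object)
    if not (len(pred) == len(y) == len(strat)):
        raise ValueError("predictions, labels and stratum must have equal length")
    if not np.array_equal(strat == STRATUM_AD, y == 1):
        raise ValueError("stratum inconsistent with labels")
    ad = strat == STRATUM_AD
    t = strat == STRATUM_NONAD_T
    nt = strat == STRATUM_NONAD_NT
    return StratifiedConfusion(
        tp=int((pred[ad] == 1).sum()), fn=int((pred[ad] == 0).sum()),
        tn_t=int((pred[t] == 0).sum()), fp_t=int((pred[t] == 1).sum()),
        tn_nt=int((pred[nt] == 0).sum()), fp_nt=int((pred[nt] == 1).sum()))


def accuracy(c: StratifiedConfusion) -> float:
    """Percent of all test rows classified correctly."""
    if c.total == 0:
        raise ValueError("accuracy undefined for an empty confusion")
    return 100.0 * (c.tp + c.tn) / c.total


def recall(c: StratifiedConfusion) -> float:
    """Percent of true AD cases predicted AD; NaN if there are no cases."""
    denom = c.tp + c.fn
    return math.nan if denom == 0 else 100.0 * c.tp / denom


def error_rate_t(c: StratifiedConfusion) -> float:
    """False-positive percent among controls with thoracalgia; NaN if none."""
    denom = c.tn_t + c.fp_t
    return math.nan if denom == 0 else 100.0 * c.fp_t / denom


def error_rate_nt(c: StratifiedConfusion) -> float:
    """False-positive percent among controls without thoracalgia; NaN if none."""
    denom = c.tn_nt + c.fp_nt
    return math.nan if denom == 0 else 100.0 * c.fp_nt / denom


def metrics_row(c: StratifiedConfusion) -> dict:
    return {"accuracy": accuracy(c), "recall": recall(c),
            "error_rate_t": error_rate_t(c), "error_rate_nt": error_rate_nt(c)}


# ---------------------------------------------------------------------------
# Model comparison harness

ALL_METHODS = ("lda", "bp", "dt", "svm", "easyensemble", "rs-easyensemble")


def split_cohort(cohort: CohortTable, test_size: float = 0.25, seed: int = 0
                 ) -> tuple[CohortTable, CohortTable]:
    """Stratified train/test split preserving the three strata proportions."""
    idx_train, idx_test = train_test_split(
        np.arange(cohort.n), test_size=test_size,
        stratify=cohort.stratum, random_state=seed)

    def take(idx):
        return CohortTable(cohort.features.iloc[idx].reset_index(drop=True),
                           cohort.labels[idx], cohort.stratum[idx],
                           cohort.feature_specs, cohort.seed)

    return take(idx_train), take(idx_test)


def fit_method(method: str, cohort: CohortTable, seed: int = 0, **kw):
    """Uniform training entry point for the five (plus one) methods."""
    if method == "lda":
        return baselines.lda_fit(cohort)
    if method == "bp":
        return baselines.bp_fit(cohort, seed=seed, **kw)
    if method == "dt":
        return baselines.dt_fit(cohort, seed=seed, **kw)
    if method == "svm":
        return baselines.svm_fit(cohort, **kw)
    if method == "easyensemble":
        return ensemble.easy_ensemble_fit(cohort, seed=seed, **kw)
    if method == "rs-easyensemble":
        return ensemble.rs_easy_ensemble_fit(cohort, seed=seed, **kw)
    raise ValueError(f"unknown method {method!r}")


def predict_method(method: str, model, X: np.ndarray) -> np.ndarray:
    if method == "lda":
        return baselines.lda_predict(model, X)
    if method == "bp":
        return baselines.bp_predict(model, X)
    if method == "dt":
        return baselines.dt_predict(model, X)
    if method == "svm":
        return baselines.svm_predict(model, X)
    if method in ("easyensemble", "rs-easyensemble"):
        return ensemble.rs_predict(model, X)
    raise ValueError(f"unknown method {method!r}")


def compare_models(cohort: CohortTable, methods=ALL_METHODS,
                   test_size: float = 0.25, seeds=(0,),
                   method_kwargs: dict | None = None) -> pd.DataFrame:
    """Train each method on a stratified split and report the four metrics.

    Returns one row per method with accuracy, recall, ER_t and ER_nt averaged
    over ``seeds`` (each seed re-splits and re-trains). A method that fails
    to train is marked failed (NaN row) and the run continues. Split policy
    and seeds are recorded in ``DataFrame.attrs``.
    """
    method_kwargs = method_kwargs or {}
    rows = {}
    for method in methods:
        per_seed = []
        failed = False
        for seed in seeds:
            train, test = split_cohort(cohort, test_size=test_size, seed=seed)
            try:
                model = fit_method(method, train, seed=seed,
                                   **method_kwargs.get(method, {}))
            except Exception as exc:  # keep the comparison going
                log.warning("method %s failed to train (seed %s): %s",
                            method, seed, exc)
                failed = True
                break
            pred = predict_method(method, model, test.X)
            per_seed.append(metrics_row(tally(pred, test.labels, test.stratum)))
        if failed or not per_seed:
            rows[method] = {"accuracy": math.nan, "recall": math.nan,
                            "error_rate_t": math.nan, "error_rate_nt": math.nan,
                            "failed": True}
        else:
            agg = {k: float(np.mean([r[k] for r in per_seed]))
                   for k in per_seed[0]}
            agg["failed"] = False
            rows[method] = agg
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.attrs["test_size"] = test_size
    report.attrs["seeds"] = tuple(seeds)
    report.attrs["n"] = cohort.n
    return report


def format_report(report: pd.DataFrame) -> str:
    """Pretty text table with percents to 2 decimals and 'n/a' markers."""
    lines = [f"{'model':<18}{'accuracy':>10}{'recall':>10}{'ER_t':>10}{'ER_nt':>10}"]
    for method, row in report.iterrows():
        cells = []
        for key in ("accuracy", "recall", "error_rate_t", "error_rate_nt"):
            v = row[key]
            cells.append("n/a" if (isinstance(v, float) and math.isnan(v))
                         else f"{v:.2f}%")
        lines.append(f"{method:<18}" + "".join(f"{c:>10}" for c in cells))
    return "\n".join(lines)
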