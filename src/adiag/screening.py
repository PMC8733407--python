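"""Univariate index screening for case-control cohorts.

The modelling indexes in the source study were selected by a two-sample test
per index — an unequal-variance (Welch) t test for continuous indexes, a
Pearson chi-square test without continuity correction for categorical ones —
keeping indexes with p <= 0.001. This module reproduces that stage both from
raw cohorts and directly from printed summary statistics (mean, SD, n per
group; or a levels-by-groups count table), so published tables can be checked
without the underlying records.

Sign convention for t: the statistic is (control mean − case mean) / SE, so an
index *elevated* in AD cases carries a negative t. That is the convention the
published table uses (e.g. heart rate, higher in cases, prints −6.10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CATEGORICAL, CONTINUOUS, CohortTable
from .errors import DegenerateDataError

__all__ = [
    "SummaryRow",
    "ScreeningResult",
    "welch_t_from_summary",
    "pooled_t_from_summary",
    "pearson_chi2",
    "p_value",
    "screen_summary",
    "screen_cohort",
]

DEFAULT_ALPHA = 0.001


@dataclass(frozen=True)
class SummaryRow:
    """Printed summary statistics for one index.

    Continuous: ``stats1 = (mean, sd, n)`` for the case group and ``stats0``
    for controls. Categorical: ``table`` is an r x 2 count matrix with cases
    in the first column.
    """

    index_name: str
    kind: str
    stats1: tuple[float, float, int] | None = None
    stats0: tuple[float, float, int] | None = None
    table: np.ndarray | None = None


@dataclass(frozen=True)
class ScreeningResult:
    index_name: str
    statistic: float
    df: float
    p_value: float
    selected: bool
    test: str = ""


def welch_t_from_summary(mean_ad: float, sd_ad: float, n_ad: int,
                         mean_non: float, sd_non: float, n_non: int
                         ) -> tuple[float, float]:
    """Unequal-variance two-sample t from group summaries.

    Returns ``(t, df)`` with t = (mean_non − mean_ad) / sqrt(sd_ad²/n_ad +
    sd_non²/n_non) and Welch–Satterthwaite degrees of freedom.
    """
    if n_ad < 2 or n_non < 2:
        raise ValueError("each group needs n >= 2")
    if sd_ad < 0 or sd_non < 0:
        raise ValueError("standard deviations must be >= 0")
    v_ad = sd_ad * sd_ad / n_ad
    v_non = sd_non * sd_non / n_non
    se2 = v_ad + v_non
    if se2 == 0:
        raise DegenerateDataError("both group variances are zero")
    t = (mean_non - mean_ad) / np.sqrt(se2)
    df = se2 * se2 / (v_ad * v_ad / (n_ad - 1) + v_non * v_non / (n_non - 1))
    return float(t), float(df)


def pooled_t_from_summary(mean_ad: float, sd_ad: float, n_ad: int,
                          mean_non: float, sd_non: float, n_non: int
                          ) -> tuple[float, float]:
    """Equal-variance (pooled) two-sample t from group summaries; same sign
    convention as :func:`welch_t_from_summary`, df = n_ad + n_non − 2."""
    if n_ad < 2 or n_non < 2:
        raise ValueError("each group needs n >= 2")
    df = n_ad + n_non - 2
    sp2 = ((n_ad - 1) * sd_ad ** 2 + (n_non - 1) * sd_non ** 2) / df
    if sp2 == 0:
        raise DegenerateDataError("pooled variance is zero")
    t = (mean_non - mean_ad) / np.sqrt(sp2 * (1 / n_ad + 1 / n_non))
    return float(t), float(df)


def pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square for an r x c count table, *no* continuity
    correction; df = (r−1)(c−1). Expected counts from the margin product."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("table has a zero row or column margin")
    chi2, _, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(df)


def p_value(statistic: float, df: float, family: str) -> float:
    """Tail probability: ``t_two_sided`` (two-sided Student t) or
    ``chi2_upper`` (upper chi-square)."""
    if df <= 0:
        raise ValueError("df must be > 0")
    if family == "t_two_sided":
        return float(2.0 * stats.t.sf(abs(statistic), df))
    if family == "chi2_upper":
        return float(stats.chi2.sf(statistic, df))
    raise ValueError(f"unknown family {family!r}")


def screen_summary(rows: list[SummaryRow], alpha: float = DEFAULT_ALPHA,
                   test: str = "welch") -> list[ScreeningResult]:
    """Screen printed summary rows at threshold ``alpha`` (default 0.001)."""
    t_fn = {"welch": welch_t_from_summary, "pooled": pooled_t_from_summary}[test]
    out = []
    for row in rows:
        if row.kind == CONTINUOUS:
            stat, df = t_fn(*row.stats1, *row.stats0)
            p = p_value(stat, df, "t_two_sided")
            name = test
        else:
            stat, df = pearson_chi2(row.table)
            p = p_value(stat, df, "chi2_upper")
            name = "chi2"
        out.append(ScreeningResult(row.index_name, stat, df, p, p <= alpha, name))
    return out


def screen_cohort(cohort: CohortTable, alpha: float = DEFAULT_ALPHA,
                  test: str = "welch") -> list[ScreeningResult]:
    """One screening result per feature, in input column order.

    Continuous features get a two-sample t on the raw values; binary and
    categorical features get a chi-square on the levels-by-class contingency
    table. A feature constant across both classes yields p = 1, unselected,
    with a warning.
    """
    y = cohort.labels
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("screening needs at least 2 samples per class")
    kinds = {}
    if cohort.feature_specs:
        kinds = {s.name: s.kind for s in cohort.feature_specs}

    results = []
    for col in cohort.features.columns:
        vals = cohort.features[col].to_numpy(dtype=float)
        kind = kinds.get(col, _infer_screen_kind(vals))
        x1, x0 = vals[y == 1], vals[y == 0]
        if np.nanstd(vals) == 0:
            warnings.warn(f"feature {col!r} is constant; p set to 1", stacklevel=2)
            results.append(ScreeningResult(col, 0.0, 1.0, 1.0, False, "degenerate"))
            continue
        if kind == CONTINUOUS:
            t_fn = {"welch": welch_t_from_summary,
                    "pooled": pooled_t_from_summary}[test]
            stat, df = t_fn(float(np.mean(x1)), float(np.std(x1, ddof=1)), len(x1),
                            float(np.mean(x0)), float(np.std(x0, ddof=1)), len(x0))
            p = p_value(stat, df, "t_two_sided")
            results.append(ScreeningResult(col, stat, df, p, p <= alpha, test))
        else:
            levels = np.unique(vals)
            table = np.array([[(x1 == lv).sum(), (x0 == lv).sum()] for lv in levels],
                             dtype=float)
            stat, df = pearson_chi2(table)
            p = p_value(stat, df, "chi2_upper")
            results.append(ScreeningResult(col, stat, df, p, p <= alpha, "chi2"))
    return results


def _infer_screen_kind(values: np.ndarray) -> str:
    # {0,1,2}-coded columns (yes/no/quit convention) screen as categorical
    uniq = np.unique(values[~np.isnan(values)])
    if len(uniq) <= 3 and set(uniq) <= {0.0, 1.0, 2.0}:
        return CATEGORICAL
    return CONTINUOUS
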