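import numpy as np
import pandas as pd
import pytest

from adiag.cohort import THORACALGIA, CohortTable, derive_stratum


def cohort_from_arrays(X, y, thoracalgia=None, column_names=None, specs=None,
                       seed=None):
    """Build a CohortTable from plain arrays; stratum derived from the
    optional thoracalgia indicator."""
    X = np.asarray(X, dtype=float)
    names = column_names or [f"f{j}" for j in range(X.shape[1])]
    features = pd.DataFrame(X, columns=names)
    if thoracalgia is not None:
        features[THORACALGIA] = np.asarray(thoracalgia, dtype=float)
    stratum = derive_stratum(features, y)
    return CohortTable(features, np.asarray(y, dtype=int), stratum,
                       feature_specs=specs, seed=seed)


def separable_cohort(n_pos=50, n_neg=500, d=3, gap=10.0, seed=0,
                     with_thoracalgia=True):
    """Two Gaussian clouds `gap` standard deviations apart — any sane
    classifier separates them perfectly."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(gap, 1.0, size=(n_pos, d)),
                   rng.normal(0.0, 1.0, size=(n_neg, d))])
    y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    thor = rng.binomial(1, 0.3, size=n_pos + n_neg) if with_thoracalgia else None
    return cohort_from_arrays(X, y, thoracalgia=thor)


@pytest.fixture
def small_separable():
    return separable_cohort(n_pos=30, n_neg=300, d=4, seed=11)
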