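"""Synthetic imbalanced clinical cohorts.

The study population this package targets — aortic dissection (AD) screening
from routine clinical indexes — is severely imbalanced: roughly one AD patient
per 65 controls. The raw hospital records behind the published summary table
are not deposited, so this module generates cohorts with the same *marginal*
class-conditional structure: each continuous index is Gaussian within class
with the published mean/SD, each yes-no index Bernoulli with the published
prevalence, and smoking status a three-level categorical draw. Features are
independent given class (only marginal moments are published; see
docs/methods.md for what this leaves out).

Rows are stratified into three groups used throughout evaluation:
AD cases, non-AD patients *with* chest pain (thoracalgia) and non-AD patients
*without* chest pain. The stratum of a control is read off its simulated
thoracalgia indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import UnprocessableColumnError

__all__ = [
    "FeatureSpec",
    "CohortTable",
    "STRATUM_AD",
    "STRATUM_NONAD_T",
    "STRATUM_NONAD_NT",
    "THORACALGIA",
    "builtin_study_specs",
    "generate_cohort",
    "impute_missing",
    "specs_to_frame",
    "specs_from_frame",
]

STRATUM_AD = "AD"
STRATUM_NONAD_T = "nonAD_thoracalgia"
STRATUM_NONAD_NT = "nonAD_no_thoracalgia"

#: Column name of the chest-pain indicator that drives control stratification.
THORACALGIA = "Thoracalgia"

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class FeatureSpec:
    """Class-conditional generative parameters for one clinical index.

    ``class1_params`` describes the AD (minority, label 1) class and
    ``class0_params`` the non-AD class. The parameter dict holds
    ``{"mean", "sd"}`` for continuous indexes, ``{"prevalence"}`` for binary
    (yes=1/no=0) indexes, and ``{"levels", "probs"}`` for categorical indexes
    (e.g. smoking status: yes=1, no=0, quit=2).
    """

    name: str
    feature_id: int
    kind: str
    class0_params: dict
    class1_params: dict
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY, CATEGORICAL):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 1 <= int(self.feature_id) <= 80:
            raise ValueError(f"feature_id must be in 1..80, got {self.feature_id}")
        for params in (self.class0_params, self.class1_params):
            if self.kind == CONTINUOUS:
                if params["sd"] < 0:
                    raise ValueError(f"{self.name}: sd must be >= 0")
            elif self.kind == BINARY:
                if not 0.0 <= params["prevalence"] <= 1.0:
                    raise ValueError(f"{self.name}: prevalence outside [0, 1]")
            else:
                probs = np.asarray(params["probs"], dtype=float)
                if len(probs) != len(params["levels"]):
                    raise ValueError(f"{self.name}: levels/probs length mismatch")
                if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{self.name}: probabilities must sum to 1")


@dataclass
class CohortTable:
    """A feature matrix with outcome labels and the three-group stratum tag.

    Invariants: ``stratum == AD`` exactly where ``label == 1``; a control row
    is in the thoracalgia stratum iff its thoracalgia indicator equals 1.
    """

    features: pd.DataFrame
    labels: np.ndarray
    stratum: np.ndarray
    feature_specs: list[FeatureSpec] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.stratum = np.asarray(self.stratum, dtype=object)
        n = len(self.features)
        if len(self.labels) != n or len(self.stratum) != n:
            raise ValueError("features, labels and stratum must have equal length")
        if not np.array_equal(self.stratum == STRATUM_AD, self.labels == 1):
            raise ValueError("stratum must be AD exactly where label is 1")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def class_counts(self) -> tuple[int, int]:
        """(n_minority, n_majority) = (#AD, #non-AD)."""
        n1 = int((self.labels == 1).sum())
        return n1, len(self.labels) - n1


def _cont(name, fid, m1, s1, m0, s0, units=""):
    return FeatureSpec(name, fid, CONTINUOUS,
                       {"mean": m0, "sd": s0}, {"mean": m1, "sd": s1}, units)


def _binary(name, fid, k1, n1, k0, n0):
    return FeatureSpec(name, fid, BINARY,
                       {"prevalence": k0 / n0}, {"prevalence": k1 / n1})


# Published screened-index summary statistics of the source cohort
# (802 AD cases / 52,411 controls): AD mean±SD then control mean±SD for
# continuous indexes, AD and control event counts for yes/no indexes, and
# three-level counts (no=0 / yes=1 / quit=2) for smoking status.
_N_AD, _N_NON = 802, 52411


def builtin_study_specs() -> list[FeatureSpec]:
    """The screened modelling indexes with their published class-conditional
    parameters: the default parameterization of :func:`generate_cohort`."""
    specs = [
        _cont("Age", 1, 55.57, 12.90, 62.56, 13.06, "year"),
        _binary("Gender", 2, 574, _N_AD, 29994, _N_NON),
        _binary(THORACALGIA, 3, 206, _N_AD, 9460, _N_NON),
        _binary("Palpitation", 4, 63, _N_AD, 6106, _N_NON),
        _binary("Dizziness or headache", 5, 62, _N_AD, 7803, _N_NON),
        _binary("Aortic area murmur", 6, 23, _N_AD, 377, _N_NON),
        _binary("Chest trauma", 7, 11, _N_AD, 206, _N_NON),
        FeatureSpec("Smoking status", 8, CATEGORICAL,
                    {"levels": (0, 1, 2),
                     "probs": (12293 / _N_NON, 37121 / _N_NON, 2997 / _N_NON)},
                    {"levels": (0, 1, 2),
                     "probs": (296 / _N_AD, 485 / _N_AD, 21 / _N_AD)}),
        _cont("Time of smoking", 9, 10.22, 14.39, 7.34, 13.88, "year"),
        _binary("Hypertension", 10, 530, _N_AD, 31571, _N_NON),
        _binary("Diabetes", 11, 88, _N_AD, 11910, _N_NON),
        _cont("Time of diabetes", 12, 0.85, 2.87, 1.82, 3.83, "year"),
        _cont("Heart rate", 13, 81.74, 13.87, 78.73, 14.20, "beats/min"),
        _cont("Systolic pressure", 14, 142.41, 26.71, 136.86, 21.90, "mmHg"),
        _cont("Diastolic pressure", 15, 83.20, 16.59, 80.46, 13.01, "mmHg"),
        _cont("Neutrophil granulocyte count", 16, 7.16, 4.08, 4.79, 3.47, "10^9/L"),
        _cont("Neutrophil percentage", 17, 72.83, 10.79, 65.30, 12.09, "%"),
        _cont("Lymphocyte percentage", 18, 16.94, 9.10, 24.22, 10.44, "%"),
        _cont("Lymphocyte count", 19, 1.36, 0.60, 1.57, 2.03, "10^9/L"),
        _cont("Mean platelet volume", 20, 8.93, 1.39, 9.36, 1.58, "fl"),
        _cont("Total protein", 21, 64.58, 7.06, 65.43, 8.04, "g/L"),
        _cont("Albumin", 22, 37.08, 5.67, 38.61, 6.26, "g/L"),
        _cont("Globulin", 23, 27.57, 5.19, 26.94, 5.32, "g/L"),
        _cont("A/G", 24, 1.40, 0.36, 1.49, 0.37),
        _cont("Total bilirubin", 25, 16.19, 21.62, 13.20, 26.81, "umol/L"),
        _cont("Glutamic-pyruvic transaminase", 26, 66.50, 296.27, 32.47, 108.73, "U/L"),
        _cont("Glycated serum protein", 27, 2.25, 0.62, 2.03, 0.73, "mmol/L"),
        _cont("Lactic dehydrogenase", 28, 322.03, 684.10, 236.51, 283.48, "U/L"),
        _cont("Myohemoglobin", 29, 72.69, 84.95, 57.60, 59.02, "ug/L"),
        _cont("Potassium", 30, 3.83, 0.56, 3.97, 0.52, "mmol/L"),
        _cont("Sodium", 31, 139.37, 4.28, 140.71, 3.79, "mmol/L"),
        _cont("Chlorine", 32, 101.08, 4.95, 102.59, 4.62, "mmol/L"),
        _cont("Calcium", 33, 2.16, 0.16, 2.21, 0.18, "mmol/L"),
        _cont("Prothrombin percentage", 34, 99.83, 18.59, 106.62, 17.36, "%"),
        _cont("INR", 35, 1.06, 0.39, 1.01, 0.28),
        _cont("APTT", 36, 37.66, 11.29, 35.54, 9.68, "sec"),
        _cont("Fibrinogen", 37, 4.44, 1.81, 3.77, 1.22, "g/L"),
        _cont("D-dimer", 38, 1.37, 1.94, 0.97, 1.27, "mg/L"),
        _cont("Plasma plasminogen antigen", 39, 252.01, 24.57, 255.86, 27.68, "mg/L"),
        _cont("Prothrombin time", 40, 13.57, 4.39, 13.02, 3.06, "sec"),
    ]
    return specs


# Indexes that are physically nonnegative (durations, counts, concentrations);
# only relevant when clip_nonnegative=True.
_NONNEGATIVE_HINTS = ("time", "count", "bilirubin", "dehydrogenase",
                      "transaminase", "myohemoglobin", "d-dimer")


def _draw_feature(spec: FeatureSpec, n: int, label: int,
                  rng: np.random.Generator, clip_nonnegative: bool) -> np.ndarray:
    params = spec.class1_params if label == 1 else spec.class0_params
    if spec.kind == CONTINUOUS:
        x = rng.normal(params["mean"], params["sd"], size=n)
        if clip_nonnegative and any(h in spec.name.lower() for h in _NONNEGATIVE_HINTS):
            np.clip(x, 0.0, None, out=x)
        return x
    if spec.kind == BINARY:
        return rng.binomial(1, params["prevalence"], size=n).astype(float)
    levels = np.asarray(params["levels"], dtype=float)
    return rng.choice(levels, size=n, p=np.asarray(params["probs"], dtype=float))


def generate_cohort(
    specs: list[FeatureSpec] | None = None,
    n_minority: int = 802,
    imbalance_ratio: float = 65.35,
    seed: int = 0,
    missing_rate: float = 0.0,
    clip_nonnegative: bool = False,
) -> CohortTable:
    """Draw a synthetic cohort with exact class counts.

    ``n_minority`` AD rows plus ``round(n_minority * imbalance_ratio)``
    control rows are generated (labels fixed by design, not sampled), each
    feature drawn independently from its class-conditional law. Defaults echo
    the source study design: 802 cases at a ~1:65 imbalance. Missing cells,
    if requested, are inserted completely at random among feature cells.

    Setting ``clip_nonnegative`` truncates negative draws of physically
    nonnegative indexes at 0; this biases their sample moments upward relative
    to the nominal parameters, so it is off by default.
    """
    if n_minority < 1:
        raise ValueError(f"n_minority must be >= 1, got {n_minority}")
    if imbalance_ratio < 1:
        raise ValueError(f"imbalance_ratio must be >= 1, got {imbalance_ratio}")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError(f"missing_rate must be in [0, 1], got {missing_rate}")
    if specs is None:
        specs = builtin_study_specs()

    n_majority = int(round(n_minority * imbalance_ratio))
    n = n_minority + n_majority
    rng = np.random.default_rng(seed)

    cols = {}
    for spec in specs:
        col = np.empty(n)
        col[:n_minority] = _draw_feature(spec, n_minority, 1, rng, clip_nonnegative)
        col[n_minority:] = _draw_feature(spec, n_majority, 0, rng, clip_nonnegative)
        cols[spec.name] = col
    features = pd.DataFrame(cols)
    labels = np.concatenate([np.ones(n_minority, int), np.zeros(n_majority, int)])

    # shuffle rows so class blocks are not contiguous
    order = rng.permutation(n)
    features = features.iloc[order].reset_index(drop=True)
    labels = labels[order]

    if missing_rate > 0:
        mask = rng.random((n, len(specs))) < missing_rate
        vals = features.to_numpy()
        vals[mask] = np.nan
        features = pd.DataFrame(vals, columns=features.columns)

    stratum = derive_stratum(features, labels)
    return CohortTable(features, labels, stratum, list(specs), seed)


def derive_stratum(features: pd.DataFrame, labels: np.ndarray,
                   thoracalgia_column: str = THORACALGIA) -> np.ndarray:
    """Three-group stratum tag: AD for cases; controls split on chest pain.

    Controls with a missing or absent thoracalgia indicator fall in the
    no-thoracalgia stratum.
    """
    labels = np.asarray(labels, dtype=int)
    stratum = np.where(labels == 1, STRATUM_AD, STRATUM_NONAD_NT).astype(object)
    if thoracalgia_column in features.columns:
        thor = features[thoracalgia_column].to_numpy(dtype=float)
        with_pain = (labels == 0) & (thor == 1)
        stratum[with_pain] = STRATUM_NONAD_T
    return stratum


def impute_missing(cohort: CohortTable) -> CohortTable:
    """Fill missing feature cells: column median for continuous indexes,
    column mode for binary/categorical ones. Returns a new table."""
    features = cohort.features.copy()
    kinds = {}
    if cohort.feature_specs:
        kinds = {s.name: s.kind for s in cohort.feature_specs}

    for col in features.columns:
        vals = features[col]
        if not vals.isna().any():
            continue
        observed = vals.dropna()
        if observed.empty:
            raise UnprocessableColumnError(
                f"column {col!r} is entirely missing and cannot be imputed")
        kind = kinds.get(col, _infer_kind(observed.to_numpy()))
        if kind == CONTINUOUS:
            fill = float(observed.median())
        else:
            # mode; smallest value on ties for determinism
            fill = float(observed.mode().min())
        features[col] = vals.fillna(fill)

    stratum = derive_stratum(features, cohort.labels)
    return replace(cohort, features=features, stratum=stratum)


def _infer_kind(values: np.ndarray) -> str:
    """Heuristic used when no FeatureSpec metadata is available: columns
    whose support is within the {0, 1, 2} coding convention (yes=1, no=0,
    quit=2) are treated as categorical codes."""
    uniq = np.unique(values[~np.isnan(values)])
    if len(uniq) <= 3 and set(uniq) <= {0.0, 1.0, 2.0}:
        return CATEGORICAL
    return CONTINUOUS


# ---------------------------------------------------------------------------
# FeatureSpec <-> CSV

def specs_to_frame(specs: list[FeatureSpec]) -> pd.DataFrame:
    """One row per feature; categorical levels/probabilities ';'-joined."""
    rows = []
    for s in specs:
        row = {"name": s.name, "feature_id": s.feature_id, "kind": s.kind,
               "units": s.units}
        for cls, params in (("0", s.class0_params), ("1", s.class1_params)):
            if s.kind == CONTINUOUS:
                row[f"mean{cls}"] = params["mean"]
                row[f"sd{cls}"] = params["sd"]
            elif s.kind == BINARY:
                row[f"prevalence{cls}"] = params["prevalence"]
            else:
                row[f"levels{cls}"] = ";".join(str(v) for v in params["levels"])
                row[f"probs{cls}"] = ";".join(repr(float(p)) for p in params["probs"])
        rows.append(row)
    return pd.DataFrame(rows)


def specs_from_frame(frame: pd.DataFrame) -> list[FeatureSpec]:
    specs = []
    for _, row in frame.iterrows():
        kind = row["kind"]
        params = []
        for cls in ("0", "1"):
            if kind == CONTINUOUS:
                params.append({"mean": float(row[f"mean{cls}"]),
                               "sd": float(row[f"sd{cls}"])})
            elif kind == BINARY:
                params.append({"prevalence": float(row[f"prevalence{cls}"])})
            else:
                levels = tuple(float(v) for v in str(row[f"levels{cls}"]).split(";"))
                probs = tuple(float(v) for v in str(row[f"probs{cls}"]).split(";"))
                params.append({"levels": levels, "probs": probs})
        units = row.get("units", "")
        specs.append(FeatureSpec(row["name"], int(row["feature_id"]), kind,
                                 params[0], params[1],
                                 "" if pd.isna(units) else str(units)))
    return specs
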