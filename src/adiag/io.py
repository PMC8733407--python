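"""Cohort CSV round-tripping, sidecar metadata and model serialization.

The cohort interchange format is a plain comma-separated UTF-8 file with a
header row: one column per feature, a ``label`` column (1 = AD) and an
optional ``stratum`` column. When ``stratum`` is absent it is derived from
the thoracalgia indicator column. Floats are written with shortest-round-trip
repr so write→read is an exact identity.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (THORACALGIA, CohortTable, derive_stratum, specs_from_frame,
                     specs_to_frame)
from .errors import CohortFormatError, ModelFormatError

__all__ = [
    "read_cohort_csv", "write_cohort_csv",
    "read_specs_csv", "write_specs_csv",
    "save_model", "load_model",
    "write_screening_csv",
]

MODEL_FORMAT_VERSION = 1

_RESERVED = ("label", "stratum")


def read_cohort_csv(path, thoracalgia_column: str = THORACALGIA) -> CohortTable:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"{path}: empty file") from exc
    if "label" not in frame.columns:
        raise CohortFormatError(
            f"{path}: no 'label' column; found columns {list(frame.columns)}")

    feature_cols = [c for c in frame.columns if c not in _RESERVED]
    features = frame[feature_cols].copy()
    for col in feature_cols + ["label"]:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortFormatError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} "
                f"at row {row}, column {col!r}")
        if col != "label":
            features[col] = converted.astype(float)
    labels = pd.to_numeric(frame["label"]).to_numpy(dtype=int)

    if "stratum" in frame.columns:
        stratum = frame["stratum"].to_numpy(dtype=object)
    else:
        stratum = derive_stratum(features, labels, thoracalgia_column)
    return CohortTable(features, labels, stratum)


def write_cohort_csv(cohort: CohortTable, path, sidecar: bool = True) -> None:
    path = Path(path)
    out = cohort.features.copy()
    out["label"] = cohort.labels
    out["stratum"] = cohort.stratum
    out.to_csv(path, index=False)
    if sidecar:
        n1, n0 = cohort.class_counts()
        meta = {"seed": cohort.seed, "n": cohort.n, "n_minority": n1,
                "n_majority": n0, "columns": list(cohort.features.columns)}
        if cohort.feature_specs is not None:
            meta["specs"] = specs_to_frame(cohort.feature_specs).to_dict("records")
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))


def read_specs_csv(path):
    return specs_from_frame(pd.read_csv(path))


def write_specs_csv(specs, path) -> None:
    specs_to_frame(specs).to_csv(path, index=False)


def write_screening_csv(results, path) -> None:
    pd.DataFrame([{"index": r.index_name, "test": r.test,
                   "statistic": r.statistic, "df": r.df, "p": r.p_value,
                   "selected": r.selected} for r in results]).to_csv(
        path, index=False)


def save_model(model, path) -> None:
    """Pickle the model with a format-version tag."""
    with open(path, "wb") as fh:
        pickle.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, fh)


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path}: not an adiag model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {payload['format_version']} "
            f"!= supported {MODEL_FORMAT_VERSION}")
    return payload["model"]
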