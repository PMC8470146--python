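"""Plain-text I/O: event tables, timeseries, covariates and model JSON.

All tabular formats are tab-separated with a header row; serialised
models are JSON.  Readers validate schemas and report the offending
column and row; writers round-trip losslessly at full float precision
(floats are written with `repr` semantics).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CONDITIONS, ExperimentalDesign
from .gaussian import GaussianDensity
from .model import REGIONS, SubjectModel

__all__ = [
    "SchemaError",
    "write_events", "read_events",
    "write_timeseries", "read_timeseries",
    "write_covariates", "read_covariates",
    "write_json", "read_json",
    "write_model", "read_model",
    "write_density", "read_density",
]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


# -- events (BIDS events.tsv dialect) ---------------------------------------

#: float format that round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def write_events(design: ExperimentalDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False,
                             float_format=_FLOAT_FMT)


def read_events(path, soa_bounds=(2.0, 26.0),
                session_length: float | None = None) -> ExperimentalDesign:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ("onset", "duration", "trial_type"), path)
    for i, v in enumerate(df["trial_type"]):
        if v not in CONDITIONS:
            raise SchemaError(
                f"{path}: row {i + 2}: trial_type {v!r} not in {CONDITIONS}")
    for i, v in enumerate(df["onset"]):
        if not np.isfinite(v) or v < 0:
            raise SchemaError(f"{path}: row {i + 2}: invalid onset {v!r}")
    if "tone_hz" not in df.columns:
        df["tone_hz"] = "n/a"
    return ExperimentalDesign.from_frame(df, soa_bounds, session_length)


# -- timeseries --------------------------------------------------------------

def write_timeseries(data: pd.DataFrame, path) -> None:
    data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path, regions=REGIONS) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, regions, path)
    df = df[list(regions)]
    bad = df.columns[df.isna().any()]
    if len(bad):
        row = int(df[bad[0]].isna().idxmax())
        raise SchemaError(f"{path}: column {bad[0]!r}, row {row + 2}: missing value")
    return df


# -- covariates --------------------------------------------------------------

def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ("subject_id", "age", "rm1_amplitude"), path)
    return df


# -- JSON helpers ------------------------------------------------------------

def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_model(model: SubjectModel, path) -> None:
    write_json(model.to_dict(), path)


def read_model(path) -> SubjectModel:
    return SubjectModel.from_dict(read_json(path))


def write_density(density: GaussianDensity, path) -> None:
    write_json(density.to_dict(), path)


def read_density(path) -> GaussianDensity:
    return GaussianDensity.from_dict(read_json(path))
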