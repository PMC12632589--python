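"""Dataset and model readers/writers.

Datasets are CSV or TSV (delimiter sniffed from the header line) with a
header row of feature names and an optional leading ``id`` column. Models
serialize to a versioned JSON document whose coefficient tensor round-trips
bit-exactly (Python's shortest-repr float serialization is lossless).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataMatrix, FitConfig, ProgressionModel, build_basis

__all__ = ["read_dataset", "write_dataset", "save_model", "load_model", "MODEL_FORMAT_VERSION"]

MODEL_FORMAT_VERSION = 1


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_dataset(path, *, zscored: bool = False) -> DataMatrix:
    """Read a CSV/TSV observation-by-feature table into a DataMatrix.

    The first row is the header; a first column named ``id`` becomes the
    record ids. Non-numeric or missing cells are rejected with their
    coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    record_ids = None
    if df.columns[0].strip().lower() == "id":
        record_ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col].str.strip(), errors="coerce")
        bad = numeric.isna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            cell = df[col].iloc[i].strip()
            if cell == "":
                raise ValueError(
                    f"missing value at row {i}, column '{col}': the model accepts "
                    "no missing values; impute or drop upstream"
                )
            raise ValueError(f"non-numeric cell {cell!r} at row {i}, column '{col}'")
        values[:, j] = numeric.to_numpy()
    return DataMatrix(
        X=values, feature_names=[str(c) for c in df.columns], record_ids=record_ids,
        zscored=zscored,
    )


def write_dataset(data: DataMatrix, path, *, sep: str = ",") -> None:
    """Write a DataMatrix to CSV/TSV with an ``id`` column."""
    df = pd.DataFrame(data.X, columns=data.feature_names)
    df.insert(0, "id", data.record_ids)
    df.to_csv(path, sep=sep, index=False)


def save_model(model: ProgressionModel, path) -> None:
    """Serialize a fitted model to versioned JSON."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": list(model.feature_names),
        "K": model.config.K,
        "D": model.config.D,
        "S": model.config.S,
        "sigma": model.config.sigma,
        "l1_penalty": model.config.l1_penalty,
        "seed": model.config.seed,
        "theta": model.theta.tolist(),
        "final_loss": model.final_loss,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> ProgressionModel:
    """Load a model saved by :func:`save_model`; theta round-trips bit-exactly."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format_version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    theta = np.asarray(doc["theta"], dtype=float)
    expected = (doc["D"], len(doc["feature_names"]), doc["S"])
    if theta.shape != expected:
        raise ValueError(f"theta shape {theta.shape} does not match header {expected}")
    config = FitConfig(
        D=doc["D"],
        S=doc["S"],
        K=doc["K"],
        sigma=doc["sigma"],
        l1_penalty=doc["l1_penalty"],
        seed=doc["seed"],
    )
    return ProgressionModel(
        theta=theta,
        config=config,
        feature_names=list(doc["feature_names"]),
        final_loss=float(doc["final_loss"]),
        basis=build_basis(doc["K"], doc["D"]),
    )
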