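"""Recursive feature-dropout importance.

A fitted model's inference is repeated with one feature at a time withheld
from the likelihood sum (no refitting, and no zero-imputation — omitted
terms simply do not contribute evidence). The fraction of records whose
assignment changes measures how much the model's placements depend on that
feature; a cutoff on this importance yields a reduced feature subset for
a subsequent round of modelling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import DataMatrix, ProgressionModel, _argmax_stage_subtype

__all__ = ["dropout_report", "select_features"]


def dropout_report(model: ProgressionModel, data: DataMatrix) -> pd.DataFrame:
    """Per-feature assignment-change fractions under single-feature dropout.

    Returns a DataFrame indexed by feature with columns
    ``changed_subtype_fraction``, ``changed_stage_fraction`` and
    ``importance`` (fraction of records changing subtype OR stage).
    """
    if data.n_features < 2:
        raise ValueError("dropout requires at least 2 features (nothing to withhold)")
    if list(data.feature_names) != list(model.feature_names):
        raise ValueError("data feature names do not match the model")

    M = model.evaluate()  # (K+1, P, S)
    constants = model.constants
    # per-feature log-density contributions: (N, S, K+1, P)
    mu = np.transpose(M, (2, 0, 1))  # (S, K+1, P)
    diff = data.X[:, None, None, :] - mu[None]
    contrib = constants.log_alpha - diff**2 / constants.beta
    total = contrib.sum(axis=3)  # (N, S, K+1)

    base_s, base_k, _ = _argmax_stage_subtype(total)
    n = data.n_records
    rows = []
    for p, name in enumerate(data.feature_names):
        sub_s, sub_k, _ = _argmax_stage_subtype(total - contrib[:, :, :, p])
        changed_subtype = float((sub_s != base_s).mean())
        changed_stage = float((sub_k != base_k).mean())
        importance = float(((sub_s != base_s) | (sub_k != base_k)).mean())
        rows.append(
            {
                "feature": name,
                "changed_subtype_fraction": changed_subtype,
                "changed_stage_fraction": changed_stage,
                "importance": importance,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def select_features(report: pd.DataFrame, cutoff: float) -> list[str]:
    """Features whose dropout importance strictly exceeds ``cutoff``.

    Original feature order is preserved. An empty result emits a warning
    rather than an error.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0, 1]")
    selected = [str(f) for f in report.index[report["importance"] > cutoff]]
    if not selected:
        warnings.warn(
            f"no feature exceeds the importance cutoff {cutoff}; returning an empty list",
            stacklevel=2,
        )
    return selected
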