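"""Residualization-based normative z-scoring.

Each progression feature is regressed on confounders (age, sex, ...) within
a control sample; observations are then expressed as standardized residuals
from that control model: z = (y - y_hat) / s_eps, where s_eps is the
standard deviation of the control-model residuals. A z of 0 therefore means
"exactly the value a control with these confounders would be expected to
show", which is what anchors stage 0 of the progression model.

Categorical confounders (e.g. sex) must be numerically encoded by the
caller; all confounders are treated as numeric regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DataMatrix

__all__ = ["NormativeModel", "fit_normative", "zscore"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormativeModel:
    """Per-feature control regression coefficients and residual scales.

    ``coefficients`` has shape (Q+1, P): row 0 is the intercept, rows 1..Q
    the confounder slopes. ``residual_std`` uses the unbiased denominator
    C - Q - 1.
    """

    coefficients: np.ndarray
    residual_std: np.ndarray
    confounder_names: list[str]
    feature_names: list[str]


def _design(confounders: np.ndarray) -> np.ndarray:
    c = np.asarray(confounders, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return np.column_stack([np.ones(c.shape[0]), c])


def fit_normative(
    controls: np.ndarray,
    confounders: np.ndarray | None = None,
    *,
    feature_names: list[str] | None = None,
    confounder_names: list[str] | None = None,
) -> NormativeModel:
    """Fit per-feature OLS of control feature values on confounders + intercept.

    ``confounders`` may be None or a zero-column matrix, in which case the
    model reduces to the control mean and standard deviation per feature.
    Controls with missing confounder values are dropped with a logged count.
    """
    Y = np.asarray(controls, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    C, P = Y.shape
    if confounders is None:
        confounders = np.empty((C, 0))
    X = np.asarray(confounders, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Q = X.shape[1]
    if confounder_names is None:
        confounder_names = [f"c{j}" for j in range(Q)]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(P)]
    if len(confounder_names) != Q:
        raise ValueError("confounder_names length does not match confounder columns")

    keep = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    dropped = C - int(keep.sum())
    if dropped:
        logger.info("dropped %d control rows with missing values", dropped)
        X, Y = X[keep], Y[keep]
        C = X.shape[0]
    if C <= Q + 1:
        raise ValueError(
            f"need more than Q+1={Q + 1} control rows to fit the normative model, got {C}"
        )

    design = _design(X) if Q else np.ones((C, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which confounder columns are redundant given the others
        collinear = []
        for j in range(Q):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(confounder_names[j])
        raise ValueError(
            f"confounder design matrix is rank deficient; collinear columns: {collinear}"
        )

    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    residuals = Y - design @ beta
    dof = C - Q - 1
    residual_std = np.sqrt((residuals**2).sum(axis=0) / dof)
    scale = np.maximum(np.abs(Y).max(axis=0), 1.0)
    degenerate = np.flatnonzero(residual_std <= 1e-10 * scale)
    if degenerate.size:
        names = [feature_names[j] for j in degenerate]
        raise ValueError(f"features with zero residual variance in controls: {names}")
    if Q == 0:
        beta = beta.reshape(1, P)
    return NormativeModel(
        coefficients=beta,
        residual_std=residual_std,
        confounder_names=list(confounder_names),
        feature_names=list(feature_names),
    )


def zscore(
    model: NormativeModel,
    observations: np.ndarray,
    confounders: np.ndarray | None = None,
    *,
    record_ids: list[str] | None = None,
    confounder_names: list[str] | None = None,
) -> DataMatrix:
    """Z-score observations against the fitted control model.

    Each entry is the observed value minus the control-model prediction,
    divided by the feature's control residual standard deviation. The
    returned DataMatrix carries the ``zscored`` provenance flag.
    """
    Y = np.asarray(observations, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Q = len(model.confounder_names)
    if confounder_names is not None and list(confounder_names) != model.confounder_names:
        raise ValueError(
            f"confounder names {list(confounder_names)} do not match the fitted "
            f"model's {model.confounder_names} (order matters)"
        )
    if Q == 0:
        design = np.ones((Y.shape[0], 1))
    else:
        if confounders is None:
            raise ValueError(f"model was fitted with confounders {model.confounder_names}")
        design = _design(confounders)
        if design.shape[1] != Q + 1:
            raise ValueError(
                f"expected {Q} confounder columns ({model.confounder_names}), "
                f"got {design.shape[1] - 1}"
            )
    predicted = design @ model.coefficients
    Z = (Y - predicted) / model.residual_std
    return DataMatrix(
        X=Z,
        feature_names=list(model.feature_names),
        record_ids=record_ids,
        zscored=True,
    )
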