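"""Cross-validated subtype sweep and the six model-evaluation metrics.

Choosing the subtype count and polynomial order is an ill-posed model
selection problem, so instead of a single criterion the sweep fits a grid
of (order, subtype count) combinations across cross-validation folds and
reports six complementary metrics per fitted model, computed on that
model's held-out fold. The user inspects the metric distributions (e.g. as
boxplots) and selects a configuration; no automatic choice is made.

Metric conventions for degenerate cases are explicit: with a single
subtype the evaluation distance is 0 by convention and the silhouette is
NaN (undefined); subtypes with too few assigned records are skipped by the
correlation comparison, and an all-skipped metric is NaN.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .core import (
    Assignment,
    DataMatrix,
    ProgressionModel,
    dataset_loglik,
    fit,
    predict,
)

__all__ = [
    "run_sweep",
    "metric_stage_distribution",
    "metric_evaluation_distance",
    "metric_silhouette",
    "metric_correlation_comparison",
    "metric_aic",
    "metric_euclidean_r2",
    "compute_metrics",
]

METRIC_NAMES = [
    "stage_distribution",
    "evaluation_distance",
    "silhouette",
    "correlation_comparison",
    "aic",
    "euclidean_r2",
]


def metric_stage_distribution(assignments: list[Assignment], K: int) -> float:
    """Population standard deviation of the per-stage assignment counts.

    Lower is better: the data spreads evenly over the inferred progression.
    """
    if not assignments:
        raise ValueError("assignments must be nonempty")
    counts = np.bincount([a.stage for a in assignments], minlength=K + 1).astype(float)
    return float(counts.std())  # denominator K+1 (population form)


def metric_evaluation_distance(M: np.ndarray) -> float:
    """Mean between-subtype trajectory separation.

    Average over unordered subtype pairs of the mean Euclidean distance
    between corresponding stage rows; 0 by convention for a single subtype.
    """
    S = M.shape[2]
    if S == 1:
        return 0.0
    dists = []
    for a in range(S):
        for b in range(a + 1, S):
            dists.append(np.linalg.norm(M[:, :, a] - M[:, :, b], axis=1).mean())
    return float(np.mean(dists))


def metric_silhouette(data: DataMatrix, M: np.ndarray, assignments: list[Assignment]) -> float:
    """Mean silhouette of records against stage-centroids of other subtypes.

    a = distance to the assigned stage-centroid; b = minimum distance over
    every stage-centroid of every other subtype; silhouette = (b-a)/max(a,b).
    NaN for a single-subtype model (no "other" subtype exists).
    """
    S = M.shape[2]
    if S < 2:
        return float("nan")
    X = data.X
    vals = np.empty(X.shape[0])
    for n, asn in enumerate(assignments):
        s = asn.subtype - 1
        a = np.linalg.norm(X[n] - M[asn.stage, :, s])
        others = [t for t in range(S) if t != s]
        b = min(np.linalg.norm(X[n] - M[:, :, t], axis=1).min() for t in others)
        denom = max(a, b)
        vals[n] = 0.0 if denom == 0 else (b - a) / denom
    return float(vals.mean())


def metric_correlation_comparison(
    data: DataMatrix,
    M: np.ndarray,
    assignments: list[Assignment],
    min_records: int = 3,
) -> float:
    """Correlation between data-estimated and trajectory-implied covariances.

    Per subtype: Pearson correlation between the upper triangle (including
    the diagonal) of the feature covariance of its assigned records and the
    same triangle of the covariance of its evaluated stage rows; averaged
    over subtypes with at least ``min_records`` records and nonzero
    variance in both triangles. NaN when no subtype qualifies.
    """
    S = M.shape[2]
    labels = np.array([a.subtype for a in assignments])
    iu = np.triu_indices(data.n_features)
    scores = []
    for s in range(1, S + 1):
        rows = data.X[labels == s]
        if rows.shape[0] < min_records:
            continue
        cov_data = np.cov(rows, rowvar=False).reshape(data.n_features, data.n_features)[iu]
        cov_model = np.cov(M[:, :, s - 1], rowvar=False).reshape(
            data.n_features, data.n_features
        )[iu]
        if cov_data.std() == 0 or cov_model.std() == 0:
            continue
        scores.append(float(np.corrcoef(cov_data, cov_model)[0, 1]))
    return float(np.mean(scores)) if scores else float("nan")


def metric_aic(model: ProgressionModel, data: DataMatrix) -> float:
    """Akaike information criterion: 2*(D*P*S) - 2*dataset log-likelihood."""
    n_params = model.config.D * data.n_features * model.config.S
    loglik = dataset_loglik(data.X, model.theta, model.basis, model.constants)
    return 2.0 * n_params - 2.0 * loglik


def metric_euclidean_r2(
    data: DataMatrix, M: np.ndarray, assignments: list[Assignment]
) -> float:
    """Variance explained by the assigned stage-centroids.

    1 - sum ||x_n - mu_assigned(n)||^2 / sum ||x_n - x_bar||^2; NaN when the
    total sum of squares is zero.
    """
    X = data.X
    mu = np.stack([M[a.stage, :, a.subtype - 1] for a in assignments])
    ss_res = float(((X - mu) ** 2).sum())
    ss_tot = float(((X - X.mean(axis=0)) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def compute_metrics(
    model: ProgressionModel, data: DataMatrix, assignments: list[Assignment] | None = None
) -> dict[str, float]:
    """All six evaluation metrics of one model on one dataset."""
    if assignments is None:
        assignments = predict(model, data)
    M = model.evaluate()
    return {
        "stage_distribution": metric_stage_distribution(assignments, model.config.K),
        "evaluation_distance": metric_evaluation_distance(M),
        "silhouette": metric_silhouette(data, M, assignments),
        "correlation_comparison": metric_correlation_comparison(data, M, assignments),
        "aic": metric_aic(model, data),
        "euclidean_r2": metric_euclidean_r2(data, M, assignments),
    }


def run_sweep(
    data: DataMatrix,
    orders: list[int] = (1, 2, 3),
    subtype_counts: list[int] = (1, 2, 3, 4),
    folds: int = 10,
    config: "FitConfig | None" = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the (order x subtype count x fold) grid and evaluate each model.

    Each model is trained on a (folds-1)/folds training split from a seeded
    partition and all six metrics are computed on its held-out fold, so
    overfitting configurations are penalized. With the defaults (3 orders,
    4 subtype counts, 10 folds) 120 models are fitted. Returns a DataFrame
    with one row per (order, subtypes, fold).
    """
    from .core import FitConfig

    if folds < 2:
        raise ValueError("folds must be at least 2")
    if data.n_records < folds:
        raise ValueError(
            f"need at least {folds} records for {folds}-fold cross-validation, "
            f"got {data.n_records}"
        )
    if config is None:
        config = FitConfig(D=max(orders), S=max(subtype_counts))
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(data.X))
    rng = np.random.default_rng(seed)

    rows = []
    for order in orders:
        for S in subtype_counts:
            for fold_idx, (train_idx, test_idx) in enumerate(splits):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                cfg = replace(config, D=int(order), S=int(S), seed=sub_seed)
                train = DataMatrix(
                    X=data.X[train_idx],
                    feature_names=list(data.feature_names),
                    record_ids=[data.record_ids[i] for i in train_idx],
                    zscored=data.zscored,
                )
                test = DataMatrix(
                    X=data.X[test_idx],
                    feature_names=list(data.feature_names),
                    record_ids=[data.record_ids[i] for i in test_idx],
                    zscored=data.zscored,
                )
                model = fit(train, cfg)
                metrics = compute_metrics(model, test)
                rows.append(
                    {"order": order, "subtypes": S, "fold": fold_idx, **metrics,
                     "train_loss": model.final_loss}
                )
    return pd.DataFrame(rows)
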