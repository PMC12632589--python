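"""Plotting suite for qualitative model evaluation.

Best-effort figure generation: each panel that cannot be drawn is logged
and skipped rather than aborting the run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import Assignment, DataMatrix, ProgressionModel, observation_loglik
from .model_selection import METRIC_NAMES

__all__ = ["plot_trajectories", "plot_stage_histogram", "plot_sweep", "plot_record_likelihood", "plot_suite"]

logger = logging.getLogger(__name__)


def plot_trajectories(
    model: ProgressionModel,
    data: DataMatrix,
    assignments: list[Assignment],
    feature: str,
    ax=None,
):
    """One feature's fitted trajectory per subtype with assigned data overlay."""
    if ax is None:
        _, ax = plt.subplots()
    p = list(model.feature_names).index(feature)
    M = model.evaluate()
    K = model.config.K
    stages = np.arange(K + 1)
    for s in range(model.config.S):
        ax.plot(stages, M[:, p, s], label=f"subtype {s + 1}")
    jitter = np.random.default_rng(0).uniform(-0.15, 0.15, data.n_records)
    ax.scatter(
        [a.stage + j for a, j in zip(assignments, jitter)],
        data.X[:, p],
        s=8,
        alpha=0.4,
        c=[a.subtype for a in assignments],
        cmap="tab10",
    )
    ax.set_xlabel("stage")
    ax.set_ylabel(f"{feature} (z)")
    ax.legend(fontsize="small")
    return ax


def plot_stage_histogram(assignments: list[Assignment], K: int, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    counts = np.bincount([a.stage for a in assignments], minlength=K + 1)
    ax.bar(np.arange(K + 1), counts)
    ax.set_xlabel("stage")
    ax.set_ylabel("records")
    return ax


def plot_sweep(report: pd.DataFrame, out_dir) -> list[Path]:
    """One boxplot figure per sweep metric, grouped by (order, subtypes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for metric in METRIC_NAMES:
        fig, ax = plt.subplots(figsize=(8, 4))
        groups = report.groupby(["order", "subtypes"])[metric]
        labels, series = zip(*[(f"D{o}/S{s}", g.dropna().values) for (o, s), g in groups])
        ax.boxplot(series, tick_labels=labels)
        ax.set_ylabel(metric)
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        path = out_dir / f"sweep_{metric}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written


def plot_record_likelihood(model: ProgressionModel, data: DataMatrix, record: int, ax=None):
    """Subtype-by-stage log-likelihood heatmap for one record (S x K+1)."""
    if ax is None:
        _, ax = plt.subplots()
    phi = observation_loglik(data.X[record], model.evaluate(), model.constants)
    im = ax.imshow(phi, aspect="auto", origin="lower")
    ax.set_xlabel("stage")
    ax.set_ylabel("subtype")
    ax.set_yticks(range(model.config.S), [str(s + 1) for s in range(model.config.S)])
    plt.colorbar(im, ax=ax, label="log-likelihood")
    return ax


def plot_suite(
    model: ProgressionModel,
    data: DataMatrix,
    assignments: list[Assignment],
    out_dir,
    features: list[str] | None = None,
) -> list[Path]:
    """Write the full qualitative-evaluation figure set to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for feature in features if features is not None else model.feature_names:
        try:
            fig, ax = plt.subplots()
            plot_trajectories(model, data, assignments, feature, ax=ax)
            path = out_dir / f"trajectory_{feature}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
        except Exception:  # pragma: no cover - best effort
            logger.exception("skipping trajectory panel for %s", feature)
    try:
        fig, ax = plt.subplots()
        plot_stage_histogram(assignments, model.config.K, ax=ax)
        path = out_dir / "stage_histogram.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    except Exception:  # pragma: no cover
        logger.exception("skipping stage histogram")
    try:
        fig, ax = plt.subplots()
        plot_record_likelihood(model, data, 0, ax=ax)
        path = out_dir / "record0_likelihood.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    except Exception:  # pragma: no cover
        logger.exception("skipping likelihood heatmap")
    return written
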