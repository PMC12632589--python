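"""Ground-truth polynomial progression simulator.

Generates cross-sectional datasets from known per-subtype polynomial
trajectories so that staging and subtyping recovery can be measured
against the truth. Feature coefficient vectors are drawn around a set of
"coefficient clusters" (groups of features that progress similarly); each
subtype gets its own, independently drawn cluster means unless
``shared_clusters`` is set. Stage-sampling bias is modelled by drawing
each record's continuous stage from a per-subtype Beta distribution, and
class/cluster imbalance is targeted through the Atkinson inequality index
of the membership proportions.

The generated feature values are on the z-score scale by construction
(zero value at stage 0, additive Gaussian noise in the same units), so the
sampled DataMatrix carries the z-scoring provenance flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DataMatrix

__all__ = [
    "GeneratorParams",
    "SimulationTruth",
    "atkinson_index",
    "proportions_for_target",
    "generate_truth",
    "sample_dataset",
    "simulate_dataset",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameterization of the progression generator.

    means_range: range of cluster coefficient-mean magnitudes; larger
        values give curvier, more extreme trajectories.
    stdev_min/stdev_max: bounds on the per-cluster coefficient spread
        (cluster heterogeneity).
    noise_min/noise_max: bounds on the per-feature additive noise
        coefficient, in z-score units.
    n_subtypes: ground-truth subtype count.
    dimensions: ground-truth polynomial order.
    n_polynomials: feature count.
    n_clusters: number of coefficient clusters (<= n_polynomials).
    sampling_bias_minmax: range from which each subtype's Beta(a, b)
        stage-sampling shapes are drawn.
    polydist_imbalance_index: target Atkinson inequality of cluster sizes.
    subtype_class_imbalance_index: target Atkinson inequality of subtype
        membership (0 = balanced classes).
    record_count: number of sampled observations.
    shared_clusters: reuse the first subtype's cluster means for all
        subtypes (less separable truth); by default each subtype's means
        are drawn independently.
    shared_sampling_bias: draw one Beta(a, b) pair and use it for every
        subtype (no between-subtype sampling-bias difference).
    """

    means_range: tuple[float, float] = (1.0, 4.0)
    stdev_min: float = 0.2
    stdev_max: float = 0.5
    noise_min: float = 0.2
    noise_max: float = 1.5
    n_subtypes: int = 2
    dimensions: int = 2
    n_polynomials: int = 20
    n_clusters: int = 4
    sampling_bias_minmax: tuple[float, float] = (1.0, 4.0)
    polydist_imbalance_index: float = 0.1
    subtype_class_imbalance_index: float = 0.1
    record_count: int = 500
    seed: int = 0
    shared_clusters: bool = False
    shared_sampling_bias: bool = False

    def __post_init__(self):
        if self.stdev_min > self.stdev_max or self.stdev_min <= 0:
            raise ValueError("require 0 < stdev_min <= stdev_max")
        if self.noise_min > self.noise_max or self.noise_min < 0:
            raise ValueError("require 0 <= noise_min <= noise_max")
        if self.n_subtypes < 1 or self.dimensions < 1 or self.n_polynomials < 1:
            raise ValueError("n_subtypes, dimensions and n_polynomials must be positive")
        if not (1 <= self.n_clusters <= self.n_polynomials):
            raise ValueError(
                f"n_clusters must be in [1, n_polynomials={self.n_polynomials}], "
                f"got {self.n_clusters}"
            )
        if not (0.0 <= self.polydist_imbalance_index < 1.0):
            raise ValueError("polydist_imbalance_index must be in [0, 1)")
        if not (0.0 <= self.subtype_class_imbalance_index < 1.0):
            raise ValueError("subtype_class_imbalance_index must be in [0, 1)")
        if self.record_count < 1:
            raise ValueError("record_count must be positive")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated dataset."""

    theta_true: np.ndarray  # (dimensions, n_polynomials, n_subtypes)
    cluster_assignment: np.ndarray  # (n_polynomials,) feature -> cluster
    noise_coefficients: np.ndarray  # (n_polynomials,)
    beta_shapes: np.ndarray  # (n_subtypes, 2) stage-sampling Beta(a, b)
    record_subtype: np.ndarray  # (record_count,) 1-based labels
    record_stage: np.ndarray  # (record_count,) continuous in [0, 1]
    params: GeneratorParams
    subtype_proportions: np.ndarray = field(default=None)  # type: ignore[assignment]


def atkinson_index(proportions) -> float:
    """Atkinson inequality of a proportion vector, aversion parameter 1.

    Equals 1 - geometric_mean / arithmetic_mean: 0 for perfect equality,
    approaching 1 as the mass concentrates on one class.
    """
    p = np.asarray(proportions, dtype=float)
    if (p <= 0).any():
        raise ValueError("all proportions must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    geometric = np.exp(np.log(p).mean())
    return float(1.0 - geometric / p.mean())


def proportions_for_target(n_classes: int, target_index: float) -> np.ndarray:
    """Proportions from the geometric family p_i ~ r**i hitting a target
    Atkinson index, with the ratio r found by bisection."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if target_index < 0:
        raise ValueError("target_index must be nonnegative")
    if target_index == 0.0:
        return np.full(n_classes, 1.0 / n_classes)

    def props(r: float) -> np.ndarray:
        w = r ** np.arange(n_classes, dtype=float)
        return w / w.sum()

    lo, hi = 1e-9, 1.0  # index is decreasing in r; r=1 gives index 0
    achievable = atkinson_index(props(lo))
    if target_index >= achievable:
        raise ValueError(
            f"target Atkinson index {target_index} unreachable for the geometric "
            f"family with {n_classes} classes (achievable range [0, {achievable:.6f}))"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if atkinson_index(props(mid)) > target_index:
            lo = mid
        else:
            hi = mid
        if abs(atkinson_index(props(hi)) - target_index) < 1e-9:
            break
    return props(hi)


def _integer_sizes(proportions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment with a floor of 1 per class."""
    raw = proportions * total
    sizes = np.maximum(np.floor(raw).astype(int), 1)
    while sizes.sum() > total:
        sizes[np.argmax(sizes)] -= 1
    remainder = raw - np.floor(raw)
    while sizes.sum() < total:
        order = np.argsort(-remainder)
        for j in order:
            if sizes.sum() == total:
                break
            sizes[j] += 1
            remainder[j] = -1.0
    return sizes


def _class_proportions(n_classes: int, target: float) -> np.ndarray:
    if n_classes == 1:
        return np.array([1.0])
    return proportions_for_target(n_classes, target)


def generate_truth(params: GeneratorParams) -> SimulationTruth:
    """Draw ground-truth trajectories, noise, sampling bias and record placements.

    Deterministic given ``params.seed``. The procedure: draw cluster
    coefficient means (magnitude uniform in means_range, random sign) per
    subtype; apportion features to clusters targeting the cluster-size
    Atkinson index; draw each feature's coefficients around its cluster
    mean with a per-cluster spread; draw per-feature noise coefficients and
    per-subtype Beta stage-sampling shapes; finally draw record subtypes
    (targeting the class-imbalance index) and continuous stages.
    """
    rng = np.random.default_rng(params.seed)
    D, P, S = params.dimensions, params.n_polynomials, params.n_subtypes
    lo_mean, hi_mean = params.means_range

    cluster_props = _class_proportions(params.n_clusters, params.polydist_imbalance_index)
    sizes = _integer_sizes(cluster_props, P)
    cluster_assignment = rng.permutation(np.repeat(np.arange(params.n_clusters), sizes))

    theta_true = np.empty((D, P, S))
    for s in range(S):
        if s == 0 or not params.shared_clusters:
            magnitudes = rng.uniform(lo_mean, hi_mean, size=(params.n_clusters, D))
            signs = rng.choice([-1.0, 1.0], size=(params.n_clusters, D))
            cluster_means = magnitudes * signs
            cluster_stdev = rng.uniform(params.stdev_min, params.stdev_max, size=params.n_clusters)
        for p in range(P):
            c = cluster_assignment[p]
            theta_true[:, p, s] = rng.normal(cluster_means[c], cluster_stdev[c])

    noise_coefficients = rng.uniform(params.noise_min, params.noise_max, size=P)

    beta_shapes = rng.uniform(*params.sampling_bias_minmax, size=(S, 2))
    if params.shared_sampling_bias:
        beta_shapes = np.tile(beta_shapes[0], (S, 1))

    subtype_props = _class_proportions(S, params.subtype_class_imbalance_index)
    record_subtype = rng.choice(S, size=params.record_count, p=subtype_props) + 1
    record_stage = rng.beta(
        beta_shapes[record_subtype - 1, 0], beta_shapes[record_subtype - 1, 1]
    )

    return SimulationTruth(
        theta_true=theta_true,
        cluster_assignment=cluster_assignment,
        noise_coefficients=noise_coefficients,
        beta_shapes=beta_shapes,
        record_subtype=record_subtype,
        record_stage=record_stage,
        params=params,
        subtype_proportions=subtype_props,
    )


def sample_dataset(truth: SimulationTruth) -> DataMatrix:
    """Sample observed feature values from the ground truth.

    Record n's feature p is the subtype-s polynomial evaluated at the
    record's continuous stage plus noise_coefficient(p) * standard-normal
    noise. Deterministic given the truth's generator seed.
    """
    params = truth.params
    D, P = params.dimensions, params.n_polynomials
    # separate stream so the truth and the noise draw are independently reproducible
    rng = np.random.default_rng([params.seed, 7919])
    powers = truth.record_stage[:, None] ** np.arange(1, D + 1)[None, :]  # (N, D)
    coef = truth.theta_true[:, :, truth.record_subtype - 1]  # (D, P, N)
    exact = np.einsum("nd,dpn->np", powers, coef)
    noise = rng.standard_normal(exact.shape) * truth.noise_coefficients[None, :]
    X = exact + noise
    names = [f"poly{p}" for p in range(P)]
    ids = [f"rec{n}" for n in range(params.record_count)]
    return DataMatrix(X=X, feature_names=names, record_ids=ids, zscored=True)


def simulate_dataset(params: GeneratorParams) -> tuple[DataMatrix, SimulationTruth]:
    """Convenience: generate truth and sample one dataset from it."""
    truth = generate_truth(params)
    return sample_dataset(truth), truth
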