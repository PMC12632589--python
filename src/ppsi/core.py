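"""Polynomial progression likelihood model.

The model describes each feature of a z-scored biomarker table as a
polynomial function of a latent pseudotime axis t in [0, 1], discretized
into K+1 stages (stage 0 is the normative anchor, always evaluating to
zero). S independent sets of trajectories ("subtypes") are fitted in
parallel; every observation is hard-assigned to the subtype and stage whose
multivariate Gaussian stage-cluster (fixed isotropic sigma) gives it the
highest likelihood, and the polynomial coefficients are trained by
gradient descent on the negative log-likelihood of those maximal
assignments plus an L1 penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PseudotimeBasis",
    "GaussianConstants",
    "DataMatrix",
    "Assignment",
    "FitConfig",
    "ProgressionModel",
    "FitDivergedError",
    "build_basis",
    "evaluate_progression",
    "log_pdf",
    "observation_loglik",
    "assign",
    "dataset_loglik",
    "total_loss",
    "fit",
    "predict",
]

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-8
_INIT_STD = 0.1  # near-zero start: respects the zero-intercept prior, breaks subtype symmetry
_MIN_LR_FRACTION = 0.01
_WARMUP_FRACTION = 0.1


class FitDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(
            f"training loss became non-finite at iteration {iteration}; "
            "reduce the learning rate or check the input scaling"
        )


@dataclass(frozen=True)
class PseudotimeBasis:
    """Stage-by-degree matrix T with T[k, d-1] = (k/K)**d.

    K is the number of non-zero stages, so the progression has K+1 stages
    in total (stage 0 = control anchor at t=0, stage K at t=1). D is the
    maximal polynomial degree; column d-1 holds the d-th power of t.
    """

    K: int
    D: int
    matrix: np.ndarray  # (K+1, D)

    def __post_init__(self):
        if self.matrix.shape != (self.K + 1, self.D):
            raise ValueError("basis matrix shape inconsistent with K, D")


def build_basis(K: int, D: int) -> PseudotimeBasis:
    """Construct the pseudotime basis matrix for K non-zero stages, degree D."""
    if K < 1 or D < 1:
        raise ValueError(f"K and D must be positive integers, got K={K}, D={D}")
    t = np.arange(K + 1, dtype=float) / K
    powers = np.arange(1, D + 1)
    matrix = t[:, None] ** powers[None, :]
    return PseudotimeBasis(K=int(K), D=int(D), matrix=matrix)


@dataclass(frozen=True)
class GaussianConstants:
    """Precomputed constants of the fixed-sigma normal density.

    alpha = 1/(sigma*sqrt(2*pi)) is the PDF coefficient and beta = 2*sigma**2
    the exponent denominator; precomputing them lets the log-density reduce
    to ``ln(alpha) - (x - mu)**2 / beta`` with no per-call transcendentals
    beyond the square.
    """

    sigma: float
    alpha: float
    beta: float
    log_alpha: float

    @classmethod
    def from_sigma(cls, sigma: float) -> "GaussianConstants":
        if sigma <= 0:
            raise ValueError(f"sigma must be positive, got {sigma}")
        alpha = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
        beta = 2.0 * sigma**2
        return cls(sigma=float(sigma), alpha=alpha, beta=beta, log_alpha=math.log(alpha))


@dataclass
class DataMatrix:
    """N-by-P observation table of z-scored feature values.

    Missing values are rejected: imputation is the caller's responsibility.
    ``zscored`` is a provenance flag set by the normative z-scoring step;
    fitting on data without it only logs a warning, since z-scoring is an
    assumption of the model rather than an enforceable contract.
    """

    X: np.ndarray
    feature_names: list[str]
    record_ids: list[str] | None = None
    zscored: bool = False

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise ValueError("X must have at least one record and one feature")
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"X contains a missing/non-finite value at record {bad[0]}, "
                f"feature '{self.feature_names[bad[1]]}'; resolve missingness upstream"
            )
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match number of columns")
        if self.record_ids is None:
            self.record_ids = [str(i) for i in range(n)]
        elif len(self.record_ids) != n:
            raise ValueError("record_ids length does not match number of rows")

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class Assignment:
    """Maximum-likelihood placement of one observation.

    ``subtype`` is 1-based, ``stage`` 0-based (stage 0 = control anchor);
    ``loglik`` is the log-likelihood at the assigned cell.
    """

    subtype: int
    stage: int
    loglik: float


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of a progression model fit.

    K: number of non-zero stages (default 15).
    D: maximal polynomial degree.
    S: number of subtypes fitted in parallel.
    sigma: fixed stage-cluster standard deviation, in z-score units.
    l1_penalty: lambda weighting the L1 term of the loss.
    max_lr: peak learning rate of the annealing schedule.
    iterations: gradient steps.
    minibatch_fraction: fraction of records sampled (without replacement)
        per step; the likelihood term is rescaled by N/|batch| so the
        penalty balance is batch-size invariant.
    seed: seeds both coefficient initialization and minibatch sampling.
    """

    D: int
    S: int
    K: int = 15
    sigma: float = 1.0
    l1_penalty: float = 0.05
    max_lr: float = 0.1
    iterations: int = 2000
    minibatch_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.D < 1 or self.S < 1:
            raise ValueError("K, D and S must be positive integers")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.l1_penalty < 0:
            raise ValueError("l1_penalty must be nonnegative")
        if self.max_lr <= 0:
            raise ValueError("max_lr must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not (0.0 < self.minibatch_fraction <= 1.0):
            raise ValueError("minibatch_fraction must be in (0, 1]")


@dataclass
class ProgressionModel:
    """A fitted progression model: coefficient tensor plus hyperparameters."""

    theta: np.ndarray  # (D, P, S)
    config: FitConfig
    feature_names: list[str]
    final_loss: float
    basis: PseudotimeBasis
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        expected = (self.config.D, len(self.feature_names), self.config.S)
        if self.theta.shape != expected:
            raise ValueError(
                f"theta shape {self.theta.shape} inconsistent with config/feature "
                f"names (expected {expected})"
            )

    @property
    def constants(self) -> GaussianConstants:
        return GaussianConstants.from_sigma(self.config.sigma)

    def evaluate(self) -> np.ndarray:
        """Evaluated trajectories M, shape (K+1, P, S)."""
        return evaluate_progression(self.theta, self.basis)


def evaluate_progression(theta: np.ndarray, basis: PseudotimeBasis) -> np.ndarray:
    """Evaluate every feature polynomial of every subtype at every stage.

    Returns M of shape (K+1, P, S) with M[:, :, s] = T @ theta[:, :, s].
    Row k=0 is exactly zero for every subtype (fixed zero intercept).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 3:
        raise ValueError("theta must be a 3-D (degree, feature, subtype) tensor")
    if theta.shape[0] != basis.D:
        raise ValueError(
            f"degree dimension of theta ({theta.shape[0]}) does not match basis D ({basis.D})"
        )
    return np.einsum("kd,dps->kps", basis.matrix, theta)


def log_pdf(mu, x, constants: GaussianConstants):
    """Memoized fixed-sigma normal log-density: ln(alpha) - (x - mu)**2 / beta.

    Accepts scalars or broadcastable arrays.
    """
    mu = np.asarray(mu, dtype=float)
    x = np.asarray(x, dtype=float)
    out = constants.log_alpha - (x - mu) ** 2 / constants.beta
    return out if out.ndim else float(out)


def _loglik_cube(X: np.ndarray, M: np.ndarray, constants: GaussianConstants) -> np.ndarray:
    """Log-likelihood of every record at every (subtype, stage): (N, S, K+1)."""
    # M: (K+1, P, S) -> (S, K+1, P) for broadcasting against X: (N, P)
    mu = np.transpose(M, (2, 0, 1))
    diff = X[:, None, None, :] - mu[None, :, :, :]
    sq = np.einsum("nskp,nskp->nsk", diff, diff)
    return X.shape[1] * constants.log_alpha - sq / constants.beta


def observation_loglik(x_n: np.ndarray, M: np.ndarray, constants: GaussianConstants) -> np.ndarray:
    """Per-stage, per-subtype log-likelihood matrix for one observation.

    Entry (s, k) is the sum over features of the fixed-sigma log-density of
    the observed value given the evaluated trajectory point mu[k, p, s].
    Returned shape is (S, K+1).
    """
    x_n = np.asarray(x_n, dtype=float).ravel()
    if x_n.shape[0] != M.shape[1]:
        raise ValueError(
            f"observation has {x_n.shape[0]} features but the model expects {M.shape[1]}"
        )
    return _loglik_cube(x_n[None, :], M, constants)[0]


def _argmax_stage_subtype(phi_cube: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized argmax over (S, K+1) cells for a (N, S, K+1) cube.

    Ties break toward the lowest stage, then the lowest subtype index,
    which deterministically biases ambiguous records toward "less
    progressed" placements.
    """
    n, S, K1 = phi_cube.shape
    # order cells stage-major so np.argmax's first-occurrence rule realizes
    # the (lowest stage, then lowest subtype) tie-break
    flat = np.transpose(phi_cube, (0, 2, 1)).reshape(n, K1 * S)
    idx = np.argmax(flat, axis=1)
    stages = idx // S
    subtypes = idx % S
    logliks = flat[np.arange(n), idx]
    return subtypes, stages, logliks


def assign(phi: np.ndarray) -> Assignment:
    """Hard-assign one observation from its (S, K+1) log-likelihood matrix."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2:
        raise ValueError("phi must be an (S, K+1) matrix")
    subtypes, stages, logliks = _argmax_stage_subtype(phi[None])
    return Assignment(subtype=int(subtypes[0]) + 1, stage=int(stages[0]), loglik=float(logliks[0]))


def dataset_loglik(
    X: np.ndarray, theta: np.ndarray, basis: PseudotimeBasis, constants: GaussianConstants
) -> float:
    """Log-domain dataset likelihood: sum over records of the maximal cell."""
    M = evaluate_progression(theta, basis)
    phi = _loglik_cube(np.asarray(X, dtype=float), M, constants)
    return float(phi.max(axis=(1, 2)).sum())


def total_loss(
    data: DataMatrix,
    theta: np.ndarray,
    basis: PseudotimeBasis,
    constants: GaussianConstants,
    l1_penalty: float,
) -> float:
    """Negative maximal-assignment log-likelihood plus lambda * sum |theta|."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[1] != data.n_features:
        raise ValueError(
            f"theta has {theta.shape[1]} features but the data has {data.n_features}"
        )
    return -dataset_loglik(data.X, theta, basis, constants) + l1_penalty * float(
        np.abs(theta).sum()
    )


def _learning_rate(iteration: int, config: FitConfig) -> float:
    """Linear warmup over the first 10% of iterations, then cosine annealing
    from max_lr down to 1% of max_lr."""
    warmup = max(1, round(_WARMUP_FRACTION * config.iterations))
    if iteration < warmup:
        return config.max_lr * (iteration + 1) / warmup
    span = max(1, config.iterations - warmup)
    progress = (iteration - warmup) / span
    floor = _MIN_LR_FRACTION * config.max_lr
    return floor + 0.5 * (config.max_lr - floor) * (1.0 + math.cos(math.pi * progress))


def fit(data: DataMatrix, config: FitConfig) -> ProgressionModel:
    """Train a progression model by minibatch adaptive-moment gradient descent.

    Each iteration draws a seeded minibatch, hard-assigns its records to
    their maximum-likelihood (subtype, stage) cells, and takes an Adam step
    on the subgradient of the loss with the assignments held fixed
    (hard-assignment subgradient, as in k-means / hard EM). The likelihood
    term is rescaled by N/|batch| so the L1 penalty keeps a constant
    meaning across batch sizes. Deterministic given ``config.seed``.
    """
    import warnings

    if not data.zscored:
        warnings.warn(
            "fitting on data without the z-scoring provenance flag; the model "
            "assumes features are normative z-scores",
            stacklevel=2,
        )
    n, p = data.X.shape
    rng = np.random.default_rng(config.seed)
    theta = rng.normal(0.0, _INIT_STD, size=(config.D, p, config.S))
    # anchor the initial linear term at the per-feature data mean: with a pure
    # near-zero start, every record can fall to the zero-anchored stage 0,
    # whose gradient vanishes (T[0, :] = 0), freezing training permanently
    theta[0] += data.X.mean(axis=0)[:, None]
    basis = build_basis(config.K, config.D)
    constants = GaussianConstants.from_sigma(config.sigma)

    batch_size = min(n, math.ceil(config.minibatch_fraction * n))
    scale = n / batch_size
    lam = config.l1_penalty
    two_over_beta = 2.0 / constants.beta

    m1 = np.zeros_like(theta)
    m2 = np.zeros_like(theta)
    loss_history: list[float] = []

    for it in range(config.iterations):
        if batch_size < n:
            idx = rng.choice(n, size=batch_size, replace=False)
            Xb = data.X[idx]
        else:
            Xb = data.X
        M = evaluate_progression(theta, basis)
        phi = _loglik_cube(Xb, M, constants)
        subtypes, stages, logliks = _argmax_stage_subtype(phi)

        loss = -scale * float(logliks.sum()) + lam * float(np.abs(theta).sum())
        if not math.isfinite(loss):
            raise FitDivergedError(it)
        loss_history.append(loss)

        residual = Xb - M[stages, :, subtypes]  # (B, P)
        grad = np.zeros_like(theta)
        Tk = basis.matrix[stages]  # (B, D)
        for s in range(config.S):
            mask = subtypes == s
            if mask.any():
                grad[:, :, s] = -two_over_beta * np.einsum(
                    "bd,bp->dp", Tk[mask], residual[mask]
                )
        grad *= scale
        grad += lam * np.sign(theta)

        m1 = _ADAM_BETA1 * m1 + (1.0 - _ADAM_BETA1) * grad
        m2 = _ADAM_BETA2 * m2 + (1.0 - _ADAM_BETA2) * grad**2
        m1_hat = m1 / (1.0 - _ADAM_BETA1 ** (it + 1))
        m2_hat = m2 / (1.0 - _ADAM_BETA2 ** (it + 1))
        theta -= _learning_rate(it, config) * m1_hat / (np.sqrt(m2_hat) + _ADAM_EPS)

    final_loss = total_loss(data, theta, basis, constants, lam)
    return ProgressionModel(
        theta=theta,
        config=config,
        feature_names=list(data.feature_names),
        final_loss=final_loss,
        basis=basis,
        loss_history=loss_history,
    )


def predict(model: ProgressionModel, data: DataMatrix) -> list[Assignment]:
    """Assign every record of ``data`` to its maximum-likelihood subtype and stage."""
    if list(data.feature_names) != list(model.feature_names):
        missing = [f for f in model.feature_names if f not in data.feature_names]
        extra = [f for f in data.feature_names if f not in model.feature_names]
        raise ValueError(
            "data feature names do not match the model "
            f"(missing: {missing or 'none'}; extra: {extra or 'none'}; "
            "order must also match)"
        )
    M = model.evaluate()
    phi = _loglik_cube(data.X, M, model.constants)
    subtypes, stages, logliks = _argmax_stage_subtype(phi)
    return [
        Assignment(subtype=int(s) + 1, stage=int(k), loglik=float(l))
        for s, k, l in zip(subtypes, stages, logliks)
    ]
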