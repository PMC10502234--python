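"""The t-SNE optimization loop, exposed step by step.

The embedding minimizes KL(P || Q) where Q is the Student-t kernel

    q_ij = u_ij / Z,   u_ij = (1 + ||y_i - y_j||^2)^-1,   Z = sum_{k != l} u_kl.

The per-point gradient is

    dKL/dy_i = 4 sum_{j != i} (p_ij - q_ij) phi_ij,
    phi_ij   = (y_i - y_j) u_ij,

and the optimizer applies momentum gradient descent:

    v <- m v - eta dKL/dy,   y <- y + v.

Every per-iteration quantity (Q, phi, Z, the gradient) is exposed through
:class:`StepQuantities` so that attribution tracking can mirror the update
arithmetic exactly.  The loop itself never re-centers the embedding; the
attribution layer centers once at the end (a translation does not change the
KL objective, and avoiding per-iteration centering keeps the per-sample
update map clean to differentiate).
"""
from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._errors import OptimizationDivergedError, ParameterError
from .affinity import AffinityModel, calibrate_affinities
from .io import DataMatrix

_DIVERGENCE_LIMIT = 1e8


@dataclasses.dataclass
class OptimizerConfig:
    """Hyperparameters of the momentum gradient-descent loop."""

    n_iter: int = 1000
    learning_rate: float | str = "auto"  # "auto" -> max(n / (4 * exaggeration), 50)
    momentum: float = 0.5
    final_momentum: float = 0.8
    momentum_switch_iter: int = 250
    exaggeration_factor: float = 12.0
    exaggeration_iters: int = 250
    use_gains: bool = False
    bh_theta: float | None = None  # None -> exact O(n^2) mode
    n_components: int = 2

    def __post_init__(self):
        if self.exaggeration_iters >= self.n_iter:
            raise ParameterError("exaggeration_iters must be < n_iter")
        if self.n_components not in (2, 3):
            raise ParameterError("embedding dimension must be 2 or 3")
        if self.bh_theta is not None:
            if not (0.0 <= self.bh_theta < 1.0):
                raise ParameterError("bh_theta must lie in [0, 1)")
            if self.n_components != 2:
                raise ParameterError("Barnes-Hut mode supports 2-D embeddings only")

    def resolve_learning_rate(self, n: int) -> float:
        if self.learning_rate == "auto":
            return max(n / (4.0 * self.exaggeration_factor), 50.0)
        return float(self.learning_rate)

    def momentum_at(self, iteration: int) -> float:
        return self.momentum if iteration < self.momentum_switch_iter else self.final_momentum

    def exaggeration_at(self, iteration: int) -> float:
        return self.exaggeration_factor if iteration < self.exaggeration_iters else 1.0


@dataclasses.dataclass
class EmbeddingState:
    """Embedding coordinates plus optimizer state at one iteration."""

    Y: np.ndarray  # (n, d')
    iteration: int
    velocity: np.ndarray  # (n, d')
    rng_seed: int
    gains: np.ndarray | None = None


@dataclasses.dataclass
class StepQuantities:
    """All per-pair quantities of one t-SNE step at the current Y."""

    Q: np.ndarray  # (n, n) normalized Student-t affinities, zero diagonal
    Phi: np.ndarray  # (n, n, d') phi_ij = (y_i - y_j) u_ij
    dY: np.ndarray  # (n, d') the KL gradient 4 sum_j (p_eff - q) phi
    Z: float  # Student-t normalizer
    U: np.ndarray  # (n, n) unnormalized kernel u_ij (zero diagonal)
    diffY: np.ndarray  # (n, n, d') y_i - y_j
    exaggeration: float  # factor applied to P inside dY
    bh_summaries: dict | None = None  # quadtree kernel moments when in BH mode
    P_eff: np.ndarray | None = None  # exaggeration * P used inside dY


def student_t_kernel(Y: np.ndarray):
    """Return (U, Z, diffY) for the Student-t kernel at Y."""
    D2 = squareform(pdist(Y, metric="sqeuclidean"))
    U = 1.0 / (1.0 + D2)
    np.fill_diagonal(U, 0.0)
    Z = float(U.sum())
    diffY = Y[:, None, :] - Y[None, :, :]
    return U, Z, diffY


def compute_step_quantities(
    Y: np.ndarray, model: AffinityModel | np.ndarray, exaggeration: float = 1.0
) -> StepQuantities:
    """Exact-mode Q, phi and the KL gradient at Y for affinities P."""
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ParameterError("embedding contains non-finite values")
    P = model.P if isinstance(model, AffinityModel) else np.asarray(model)
    U, Z, diffY = student_t_kernel(Y)
    Q = U / Z
    Phi = diffY * U[:, :, None]
    P_eff = exaggeration * P
    dY = 4.0 * np.einsum("ij,ijk->ik", P_eff - Q, Phi)
    return StepQuantities(
        Q=Q, Phi=Phi, dY=dY, Z=Z, U=U, diffY=diffY, exaggeration=exaggeration, P_eff=P_eff
    )


def kl_divergence(P: np.ndarray, Y: np.ndarray) -> float:
    """KL(P || Q) over off-diagonal pairs, for monitoring convergence."""
    U, Z, _ = student_t_kernel(Y)
    Q = np.maximum(U / Z, 1e-300)
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def initial_embedding(n: int, n_components: int, seed: int) -> np.ndarray:
    """Isotropic Gaussian init (sigma = 1e-4), independent of the data."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1e-4, size=(n, n_components))


def step(
    state: EmbeddingState, quantities: StepQuantities, config: OptimizerConfig
) -> EmbeddingState:
    """Advance the embedding one iteration with momentum (and optional gains)."""
    n = state.Y.shape[0]
    lr = config.resolve_learning_rate(n)
    mom = config.momentum_at(state.iteration)
    grad = quantities.dY
    gains = state.gains
    if config.use_gains:
        if gains is None:
            gains = np.ones_like(state.Y)
        same_sign = np.sign(grad) == np.sign(state.velocity)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        gains = np.maximum(gains, 0.01)
        effective = gains * grad
    else:
        effective = grad
    velocity = mom * state.velocity - lr * effective
    Y = state.Y + velocity
    if np.max(np.abs(Y)) > _DIVERGENCE_LIMIT:
        raise OptimizationDivergedError(state.iteration + 1)
    return EmbeddingState(
        Y=Y,
        iteration=state.iteration + 1,
        velocity=velocity,
        rng_seed=state.rng_seed,
        gains=gains,
    )


@dataclasses.dataclass
class FitResult:
    """Final embedding plus recorded trajectory and KL log."""

    Y: np.ndarray
    model: AffinityModel
    config: OptimizerConfig
    seed: int
    states: list[EmbeddingState]
    kl_log: list[tuple[int, float]]

    @property
    def final_state(self) -> EmbeddingState:
        return self.states[-1]


def fit(
    X: DataMatrix | np.ndarray,
    config: OptimizerConfig | None = None,
    perplexity: float = 30.0,
    seed: int = 0,
    model: AffinityModel | None = None,
    record_every: int | None = None,
    kl_every: int = 50,
    callback: Callable[[EmbeddingState, StepQuantities], None] | None = None,
) -> FitResult:
    """Run the full t-SNE loop; deterministic given ``seed``.

    ``record_every`` keeps a stride of intermediate states (the final state is
    always kept); ``callback`` sees every (pre-update state, quantities) pair.
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    config = config or OptimizerConfig()
    if model is None:
        model = calibrate_affinities(values, perplexity)
    n = values.shape[0]
    state = EmbeddingState(
        Y=initial_embedding(n, config.n_components, seed),
        iteration=0,
        velocity=np.zeros((n, config.n_components)),
        rng_seed=seed,
    )
    states: list[EmbeddingState] = []
    kl_log: list[tuple[int, float]] = []
    if record_every:
        states.append(state)
    bh = None
    if config.bh_theta is not None:
        from . import bh as _bh

        bh = _bh
    for t in range(config.n_iter):
        ex = config.exaggeration_at(t)
        if bh is None:
            quantities = compute_step_quantities(state.Y, model, exaggeration=ex)
        else:
            quantities = bh.bh_step_quantities(state.Y, model.P, config.bh_theta, exaggeration=ex)
        if callback is not None:
            callback(state, quantities)
        state = step(state, quantities, config)
        if record_every and (state.iteration % record_every == 0):
            states.append(state)
        if kl_every and (state.iteration % kl_every == 0 or state.iteration == config.n_iter):
            kl_log.append((state.iteration, kl_divergence(model.P, state.Y)))
    if not states or states[-1].iteration != state.iteration:
        states.append(state)
    return FitResult(Y=state.Y, model=model, config=config, seed=seed, states=states, kl_log=kl_log)
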