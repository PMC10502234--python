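"""Per-sample feature attributions for t-SNE via unrolled-optimizer gradients.

The score attributed to sample i is the gradient of the squared distance of
its embedding from the embedding centroid,

    A_i = d ||y_i||^2 / d x_i = 2 y_i^T (d y_i / d x_i),

where d y_i / d x_i is propagated through every optimizer iteration by
dynamic programming.  Writing G_i^t = d y_i^t / d x_i and assuming the
cross-sample blocks d y_i / d x_j (i != j) vanish, one optimizer step
contributes

    d(grad_i)/d x_i = 4 sum_{j != i} [ (dp_ij/dx_i - dq_ij/dx_i) (x) phi_ij
                                       + (p_ij - q_ij) dphi_ij/dx_i ],

with the embedding-space partials chained through G:
dq_ij/dx_i = (dq_ij/dy_i) G_i and dphi_ij/dx_i = (dphi_ij/dy_i) G_i.
G is then advanced through the *same* momentum arithmetic the optimizer
applies to y (a velocity-derivative tensor runs alongside the velocity), so
the tracked gradient is the exact derivative of the per-sample update map
the optimizer implements under the cross-block assumption.

The closed-form embedding-space partials (d' = embedding dim):

    dq_ij/dy_i   = [ -2 u_ij^2 (y_i-y_j) + 4 q_ij sum_k u_ik^2 (y_i-y_k) ] / Z
    dphi_ij/dy_i = u_ij I - 2 u_ij^2 (y_i-y_j)(y_i-y_j)^T
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from ._errors import ContractViolation, ParameterError
from .affinity import AffinityGradient, AffinityModel, affinity_input_gradient, calibrate_affinities
from .io import DataMatrix
from .tsne import (
    EmbeddingState,
    OptimizerConfig,
    StepQuantities,
    compute_step_quantities,
    initial_embedding,
    kl_divergence,
    step,
)

VARIANTS = ("raw", "positive_only", "grad_times_input")


@dataclasses.dataclass
class GradientTensor:
    """Tracked diagonal blocks G[i] = d y_i^t / d x_i plus their velocity."""

    G: np.ndarray  # (n, d', d)
    velocity: np.ndarray  # (n, d', d), mirrors the optimizer's velocity
    iteration: int

    @classmethod
    def zero(cls, n: int, n_components: int, d: int) -> "GradientTensor":
        return cls(
            G=np.zeros((n, n_components, d)),
            velocity=np.zeros((n, n_components, d)),
            iteration=0,
        )


@dataclasses.dataclass
class AttributionMatrix:
    """Per-sample per-feature scores A (n x d)."""

    A: np.ndarray
    variant: str = "raw"
    space: str = "native"
    feature_names: list[str] | None = None


def step_partials(quantities: StepQuantities, Y: np.ndarray):
    """Full per-pair partials dq_ij/dy_i (n,n,d') and dphi_ij/dy_i (n,n,d',d')."""
    U, Q, Z, diffY = quantities.U, quantities.Q, quantities.Z, quantities.diffY
    if not np.all(np.isfinite(Y)):
        raise ParameterError("embedding contains non-finite values")
    dp = Y.shape[1]
    U2 = U * U
    s = np.einsum("ij,ijp->ip", U2, diffY)  # sum_k u_ik^2 (y_i - y_k)
    dQdY = (-2.0 * U2[:, :, None] * diffY + 4.0 * Q[:, :, None] * s[:, None, :]) / Z
    eye = np.eye(dp)
    dPhidY = U[:, :, None, None] * eye[None, None, :, :] - 2.0 * U2[
        :, :, None, None
    ] * np.einsum("ijp,ijq->ijpq", diffY, diffY)
    n = U.shape[0]
    idx = np.arange(n)
    dQdY[idx, idx, :] = 0.0
    dPhidY[idx, idx, :, :] = 0.0
    return dQdY, dPhidY


def chain_to_input(partials, G: GradientTensor):
    """Chain embedding-space partials through G: (n,n,d) and (n,n,d',d)."""
    dQdY, dPhidY = partials
    if dQdY.shape[-1] != G.G.shape[1]:
        raise ContractViolation(
            f"embedding dim mismatch: partials d'={dQdY.shape[-1]}, G d'={G.G.shape[1]}"
        )
    dQdX = np.einsum("ijp,ipd->ijd", dQdY, G.G)
    dPhidX = np.einsum("ijpq,iqd->ijpd", dPhidY, G.G)
    return dQdX, dPhidX


def update_gradient_tensor(
    G: GradientTensor,
    dPdX: AffinityGradient,
    quantities: StepQuantities,
    chained,
    config: OptimizerConfig,
    gains: np.ndarray | None = None,
) -> GradientTensor:
    """Advance G one iteration via the literal per-pair recursion.

    The gradient-of-gradient is assembled from the chained partials exactly
    as the update formula reads, then pushed through the same learning-rate /
    momentum arithmetic the optimizer applied to y at this iteration.
    """
    dQdX, dPhidX = chained
    if dQdX.shape[0] != G.G.shape[0]:
        raise ContractViolation("sample count mismatch between G and chained partials")
    if quantities.P_eff is None:
        raise ContractViolation("quantities lack P_eff; produce them via compute_step_quantities")
    Peff_minus_Q = quantities.P_eff - quantities.Q
    dPdX_eff = quantities.exaggeration * dPdX.dPdX
    dGrad = 4.0 * (
        np.einsum("ijp,ijd->ipd", quantities.Phi, dPdX_eff - dQdX)
        + np.einsum("ij,ijpd->ipd", Peff_minus_Q, dPhidX)
    )
    return _advance(G, dGrad, config, gains)


def _advance(
    G: GradientTensor, dGrad: np.ndarray, config: OptimizerConfig, gains: np.ndarray | None
) -> GradientTensor:
    n = G.G.shape[0]
    lr = config.resolve_learning_rate(n)
    mom = config.momentum_at(G.iteration)
    effective = dGrad if gains is None else gains[:, :, None] * dGrad
    velocity = mom * G.velocity - lr * effective
    return GradientTensor(G=G.G + velocity, velocity=velocity, iteration=G.iteration + 1)


def _tracked_grad(
    quantities: StepQuantities, G: np.ndarray, P: np.ndarray, dPdX: np.ndarray
) -> np.ndarray:
    """Optimized d(grad_i)/dx_i: (n, d', d).

    Uses the decomposition  dGrad = 4 [ sum_j phi (x) dp  - B G + C G ]  with

      B_i = sum_j phi_ij (x) dq_ij/dy_i = (-2/Z) M_i + (4/Z^2) s_i s_i^T
      C_i = [sum_j (p-q) u_ij] I - 2 sum_j (p-q) u^2 dd^T
      s_i = sum_j u^2 d_ij,   M_i = sum_j u^3 d_ij d_ij^T.

    In Barnes-Hut mode the q-side moments (Z, sum u^2, s, M) come from the
    quadtree; the P-weighted sums stay exact.
    """
    U, Z, diffY, Phi = quantities.U, quantities.Z, quantities.diffY, quantities.Phi
    ex = quantities.exaggeration
    Peff = ex * P
    dPdX_eff = ex * dPdX
    dp = Phi.shape[2]
    U2 = U * U
    summ = quantities.bh_summaries
    if summ is None:
        s = np.einsum("ij,ijp->ip", U2, diffY)
        M = np.einsum("ij,ij,ijp,ijq->ipq", U2, U, diffY, diffY)
        sum_u2 = U2.sum(axis=1)
    else:
        s, M, sum_u2 = summ["su2d"], summ["su3dd"], summ["su2"]
    pu = np.einsum("ij,ij->i", Peff, U)
    PU2dd = np.einsum("ij,ij,ijp,ijq->ipq", Peff, U2, diffY, diffY)
    B = (-2.0 / Z) * M + (4.0 / Z**2) * np.einsum("ip,iq->ipq", s, s)
    C = (pu - sum_u2 / Z)[:, None, None] * np.eye(dp)[None, :, :] - 2.0 * (
        PU2dd - M / Z
    )
    T1 = np.einsum("ijp,ijd->ipd", Phi, dPdX_eff)
    return 4.0 * (T1 + np.einsum("ipq,iqd->ipd", C - B, G))


@dataclasses.dataclass
class AttributionResult:
    """Everything a tracked fit produces."""

    Y: np.ndarray  # final embedding (uncentered)
    G: GradientTensor
    model: AffinityModel
    affinity_gradient: AffinityGradient
    config: OptimizerConfig
    seed: int
    X: DataMatrix
    kl_log: list[tuple[int, float]]
    checkpoints: list[tuple[int, np.ndarray]] = dataclasses.field(default_factory=list)
    loadings: np.ndarray | None = None  # PC loadings when a PCA pre-reduction ran
    X_original: DataMatrix | None = None

    @property
    def Y_centered(self) -> np.ndarray:
        return self.Y - self.Y.mean(axis=0)

    def attributions(self, variant: str = "raw", space: str = "native") -> AttributionMatrix:
        A = attributions(self.Y, self.G, self.X, variant=variant)
        A.feature_names = list(self.X.feature_names)
        if space == "pca_backprojected":
            if self.loadings is None:
                raise ParameterError("no PCA pre-reduction was performed")
            A = project_attributions(A, self.loadings)
            A.feature_names = list(self.X_original.feature_names)
        elif space != "native":
            raise ParameterError(f"unknown attribution space {space!r}")
        return A


def fit_attributions(
    X: DataMatrix | np.ndarray,
    config: OptimizerConfig | None = None,
    perplexity: float = 30.0,
    seed: int = 0,
    pca_components: int | None = None,
    checkpoint_every: int | None = None,
) -> AttributionResult:
    """Run t-SNE while tracking d y_i / d x_i; deterministic given seed.

    ``pca_components`` optionally pre-reduces the input with PCA; attributions
    can then be back-projected to the original features via the loadings.
    """
    if not isinstance(X, DataMatrix):
        X = DataMatrix.from_values(np.asarray(X, dtype=float))
    config = config or OptimizerConfig()
    X_original = None
    loadings = None
    if pca_components is not None:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=pca_components, random_state=0)
        scores = pca.fit_transform(X.values)
        loadings = pca.components_  # (m, d_orig)
        X_original = X
        X = DataMatrix.from_values(
            scores, feature_names=[f"PC{k + 1}" for k in range(pca_components)],
            sample_ids=X.sample_ids,
        )
    model = calibrate_affinities(X, perplexity)
    agrad = affinity_input_gradient(X, model)
    n, d = X.values.shape
    dp = config.n_components
    bh = None
    if config.bh_theta is not None:
        from . import bh as _bh

        bh = _bh
    state = EmbeddingState(
        Y=initial_embedding(n, dp, seed),
        iteration=0,
        velocity=np.zeros((n, dp)),
        rng_seed=seed,
    )
    G = GradientTensor.zero(n, dp, d)
    kl_log: list[tuple[int, float]] = []
    checkpoints: list[tuple[int, np.ndarray]] = []
    for t in range(config.n_iter):
        ex = config.exaggeration_at(t)
        if bh is None:
            quantities = compute_step_quantities(state.Y, model, exaggeration=ex)
        else:
            quantities = bh.bh_step_quantities(state.Y, model.P, config.bh_theta, exaggeration=ex)
        dGrad = _tracked_grad(quantities, G.G, model.P, agrad.dPdX)
        new_state = step(state, quantities, config)
        G = _advance(G, dGrad, config, new_state.gains if config.use_gains else None)
        state = new_state
        if state.iteration % 50 == 0 or state.iteration == config.n_iter:
            kl_log.append((state.iteration, kl_divergence(model.P, state.Y)))
        if checkpoint_every and state.iteration % checkpoint_every == 0:
            Yc = state.Y - state.Y.mean(axis=0)
            checkpoints.append((state.iteration, 2.0 * np.einsum("ip,ipd->id", Yc, G.G)))
    if np.abs(G.G).max() > 1e6:
        warnings.warn(
            "tracked gradients exceed 1e6: the linearized per-sample dynamics "
            "are unstable under this schedule and attributions will be noise-"
            "dominated; lower the learning rate and/or the exaggeration factor",
            RuntimeWarning,
        )
    return AttributionResult(
        Y=state.Y,
        G=G,
        model=model,
        affinity_gradient=agrad,
        config=config,
        seed=seed,
        X=X,
        kl_log=kl_log,
        checkpoints=checkpoints,
        loadings=loadings,
        X_original=X_original,
    )


def attributions(
    Y_final: np.ndarray,
    G_final: GradientTensor | np.ndarray,
    X: DataMatrix | np.ndarray | None = None,
    variant: str = "raw",
) -> AttributionMatrix:
    """A_i = 2 y_i^T G_i with y measured from the embedding centroid."""
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    G = G_final.G if isinstance(G_final, GradientTensor) else np.asarray(G_final)
    Yc = Y_final - Y_final.mean(axis=0)
    A = 2.0 * np.einsum("ip,ipd->id", Yc, G)
    if variant == "positive_only":
        A = np.where(A > 0, A, 0.0)
    elif variant == "grad_times_input":
        if X is None:
            raise ParameterError("grad_times_input requires the input matrix")
        values = X.values if isinstance(X, DataMatrix) else np.asarray(X)
        A = np.abs(A * values)
    return AttributionMatrix(A=A, variant=variant, space="native")


def project_attributions(A: AttributionMatrix, loadings: np.ndarray) -> AttributionMatrix:
    """Back-project PC-space attributions to original features: A @ loadings."""
    if A.space != "native":
        raise ParameterError("attributions are already projected")
    loadings = np.asarray(loadings, dtype=float)
    if A.A.shape[1] != loadings.shape[0]:
        raise ContractViolation(
            f"A has {A.A.shape[1]} PC features but loadings has {loadings.shape[0]} rows"
        )
    return AttributionMatrix(A=A.A @ loadings, variant=A.variant, space="pca_backprojected")


def aggregate_by_group(A: AttributionMatrix | np.ndarray, labels: Sequence):
    """Per group, the absolute value of the mean attribution row.

    Returns (group_ids, matrix) with one row per group in sorted label order.
    The absolute value is taken *after* averaging, so features that push
    members in opposite directions cancel.
    """
    values = A.A if isinstance(A, AttributionMatrix) else np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ParameterError("one label per sample required")
    groups = sorted(set(labels.tolist()))
    rows = []
    kept = []
    for g in groups:
        mask = labels == g
        if not mask.any():  # pragma: no cover - sorted(set()) never yields empty
            warnings.warn(f"group {g!r} has no members; excluded")
            continue
        rows.append(np.abs(values[mask].mean(axis=0)))
        kept.append(g)
    return kept, np.vstack(rows)
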