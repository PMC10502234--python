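"""Input-space affinities for t-SNE and their input-space derivatives.

The affinity between samples i and j is the symmetrized Gaussian conditional

    p_{j|i} = exp(-beta_i ||x_i - x_j||^2) / sum_{k != i} exp(-beta_i ||x_i - x_k||^2)
    p_ij    = (p_{j|i} + p_{i|j}) / (2 n)

with per-sample precisions beta_i = 1/(2 sigma_i^2) calibrated by bisection so
that each conditional row has perplexity 2^H equal to a user target.

Because the calibration is a root-find, the bandwidths are treated as
constants when differentiating: :func:`affinity_input_gradient` returns the
exact partial of the symmetrized p_ij with respect to x_i *with beta frozen*,
which is the quantity the attribution recursion consumes.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._errors import CalibrationError, ParameterError
from .io import DataMatrix

_P_FLOOR = 1e-12  # conditional floor, below every test tolerance
_ENTROPY_TOL = 1e-5  # tolerance on |2^H - perplexity|
_MAX_BISECT = 200


@dataclasses.dataclass
class AffinityModel:
    """Symmetrized affinities P with the calibration that produced them."""

    P: np.ndarray  # (n, n) symmetric, zero diagonal, off-diagonals sum to 1
    betas: np.ndarray  # (n,) precisions beta_i = 1/(2 sigma_i^2)
    perplexity: float
    exaggeration_factor: float = 1.0

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclasses.dataclass
class AffinityGradient:
    """dPdX[i, j] is the 1 x d row vector d p_ij / d x_i (beta frozen)."""

    dPdX: np.ndarray  # (n, n, d)
    betas_frozen: bool = True


def _sq_distances(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(X, metric="sqeuclidean"))


def _conditional_row(d2row: np.ndarray, beta: float, i: int) -> np.ndarray:
    # shift by the min off-diagonal distance for underflow safety
    w = np.exp(-beta * np.maximum(d2row - np.min(np.delete(d2row, i)), 0.0))
    w[i] = 0.0
    return w / w.sum()


def _row_perplexity(p: np.ndarray) -> float:
    nz = p > 0
    h = -np.sum(p[nz] * np.log2(p[nz]))
    return float(2.0**h)


def calibrate_affinities(X: DataMatrix | np.ndarray, perplexity: float = 30.0) -> AffinityModel:
    """Calibrate per-sample bandwidths and return symmetrized affinities.

    Parameters
    ----------
    X : DataMatrix or array
        Samples x features input.
    perplexity : float
        Target 2^entropy of every conditional row; must lie in (1, n-1].
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    n = values.shape[0]
    if n < 4:
        raise ParameterError(f"need at least 4 samples, got {n}")
    if not np.all(np.isfinite(values)):
        raise ParameterError("input matrix contains non-finite values")
    if not (1.0 < perplexity <= n - 1):
        raise ParameterError(
            f"perplexity must be in (1, n-1] = (1, {n - 1}], got {perplexity}"
        )
    D2 = _sq_distances(values)
    betas = np.empty(n)
    Pc = np.zeros((n, n))
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        p = _conditional_row(D2[i], beta, i)
        residual = _row_perplexity(p) - perplexity
        for _ in range(_MAX_BISECT):
            if abs(residual) < _ENTROPY_TOL:
                break
            if residual > 0:  # too smooth -> sharpen
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else 0.5 * (lo + hi)
            else:
                hi = beta
                beta = 0.5 * (lo + hi)
            p = _conditional_row(D2[i], beta, i)
            residual = _row_perplexity(p) - perplexity
        else:
            raise CalibrationError(i, abs(residual))
        betas[i] = beta
        Pc[i] = p
    Pc = np.maximum(Pc, _P_FLOOR)
    np.fill_diagonal(Pc, 0.0)
    P = (Pc + Pc.T) / (2.0 * n)
    return AffinityModel(P=P, betas=betas, perplexity=float(perplexity))


def conditional_probabilities(X: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Conditional p_{j|i} at fixed precisions (no calibration)."""
    X = np.asarray(X, dtype=float)
    D2 = _sq_distances(X)
    W = np.exp(-betas[:, None] * D2)
    np.fill_diagonal(W, 0.0)
    Pc = W / W.sum(axis=1, keepdims=True)
    Pc = np.maximum(Pc, _P_FLOOR)
    np.fill_diagonal(Pc, 0.0)
    return Pc


def symmetrized_probabilities(X: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Symmetrized p_ij at fixed (frozen) precisions."""
    Pc = conditional_probabilities(X, betas)
    return (Pc + Pc.T) / (2.0 * X.shape[0])


def affinity_input_gradient(
    X: DataMatrix | np.ndarray, model: AffinityModel
) -> AffinityGradient:
    """Exact d p_ij / d x_i with bandwidths held fixed.

    x_i enters p_ij three ways: the numerator of p_{j|i}, the normalizer of
    row i's conditionals, and (through the pair term w_ji) both numerator and
    normalizer of p_{i|j}.  With beta frozen all three are closed-form:

        d p_{j|i}/d x_i = -2 b_i p_{j|i} [ (x_i-x_j) - sum_k p_{k|i} (x_i-x_k) ]
        d p_{i|j}/d x_i = -2 b_j p_{i|j} (1 - p_{i|j}) (x_i-x_j)
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    n, d = values.shape
    if n < 3:
        raise ParameterError("affinity gradient undefined for n < 3 (degenerate normalizer)")
    betas = model.betas
    Pc = conditional_probabilities(values, betas)
    diff = values[:, None, :] - values[None, :, :]  # (n, n, d): x_i - x_j
    mean_i = np.einsum("ik,ikd->id", Pc, diff)  # sum_k p_{k|i} (x_i - x_k)
    d_pji = -2.0 * betas[:, None, None] * Pc[:, :, None] * (diff - mean_i[:, None, :])
    PcT = Pc.T  # PcT[i, j] = p_{i|j}
    d_pij = -2.0 * betas[None, :, None] * (PcT * (1.0 - PcT))[:, :, None] * diff
    dPdX = (d_pji + d_pij) / (2.0 * n)
    idx = np.arange(n)
    dPdX[idx, idx, :] = 0.0
    return AffinityGradient(dPdX=dPdX, betas_frozen=True)
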