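"""Literal per-pair implementation of the gradient-tracking recursion.

Every sum here is an explicit Python loop over ordered pairs, written to read
exactly like the update formulas.  It exists as an independent arithmetic
path for the optimized tracker: both must agree to near machine precision.
Only suitable for small n.
"""
from __future__ import annotations

import numpy as np

from .affinity import affinity_input_gradient, calibrate_affinities
from .io import DataMatrix
from .tsne import OptimizerConfig, initial_embedding


def dense_loop_fit(
    X,
    config: OptimizerConfig,
    perplexity: float = 30.0,
    seed: int = 0,
):
    """Tracked t-SNE fit with loop-based partials; returns (Y, G)."""
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    model = calibrate_affinities(values, perplexity)
    P = model.P
    dPdX = affinity_input_gradient(values, model).dPdX
    n, d = values.shape
    dp = config.n_components
    lr = config.resolve_learning_rate(n)
    Y = initial_embedding(n, dp, seed)
    V = np.zeros((n, dp))
    G = np.zeros((n, dp, d))
    GV = np.zeros((n, dp, d))
    eye = np.eye(dp)
    for t in range(config.n_iter):
        ex = config.exaggeration_at(t)
        mom = config.momentum_at(t)
        # per-pair kernel quantities
        U = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    dlt = Y[i] - Y[j]
                    U[i, j] = 1.0 / (1.0 + dlt @ dlt)
        Z = U.sum()
        Q = U / Z
        grad = np.zeros((n, dp))
        dGrad = np.zeros((n, dp, d))
        for i in range(n):
            s_i = np.zeros(dp)
            for k in range(n):
                if k != i:
                    s_i += U[i, k] ** 2 * (Y[i] - Y[k])
            for j in range(n):
                if j == i:
                    continue
                dlt = Y[i] - Y[j]
                phi = dlt * U[i, j]
                pq = ex * P[i, j] - Q[i, j]
                grad[i] += 4.0 * pq * phi
                dq_dy = (-2.0 * U[i, j] ** 2 * dlt + 4.0 * Q[i, j] * s_i) / Z
                dphi_dy = U[i, j] * eye - 2.0 * U[i, j] ** 2 * np.outer(dlt, dlt)
                dq_dx = dq_dy @ G[i]  # (d,)
                dphi_dx = dphi_dy @ G[i]  # (dp, d)
                dp_dx = ex * dPdX[i, j]
                dGrad[i] += 4.0 * (np.outer(phi, dp_dx - dq_dx) + pq * dphi_dx)
        V = mom * V - lr * grad
        Y = Y + V
        GV = mom * GV - lr * dGrad
        G = G + GV
    return Y, G
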