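"""Independent oracles shared by the unit and acceptance tests."""
import numpy as np

from tsnegrad.affinity import symmetrized_probabilities
from tsnegrad.tsne import fit, student_t_kernel


def reference_trajectory(X, cfg, perplexity, seed):
    """Every iterate Y^0 .. Y^T of a plain fit."""
    res = fit(X, cfg, perplexity=perplexity, seed=seed, record_every=1)
    return [s.Y for s in res.states]


def conditional_replay(X, betas, i, traj, cfg):
    """Re-integrate only y_i against the frozen reference trajectories.

    This is the map whose derivative the tracking recursion computes exactly
    under the cross-block assumption dy_j/dx_i = 0 (j != i): sample i's
    embedding is updated through the full optimizer arithmetic while every
    other sample replays its reference iterate.
    """
    P = symmetrized_probabilities(np.asarray(X, float), betas)
    n = P.shape[0]
    lr = cfg.resolve_learning_rate(n)
    yi = traj[0][i].copy()
    vi = np.zeros_like(yi)
    for t in range(cfg.n_iter):
        Y = traj[t].copy()
        Y[i] = yi
        U, Z, diffY = student_t_kernel(Y)
        Q = U / Z
        ex = cfg.exaggeration_at(t)
        grad_i = 4.0 * ((ex * P[i] - Q[i])[:, None] * (diffY[i] * U[i][:, None])).sum(axis=0)
        vi = cfg.momentum_at(t) * vi - lr * grad_i
        yi = yi + vi
    return yi


def trajectory_fd_gradient(X, betas, i, traj, cfg, h=1e-5):
    """Central finite difference of x_i -> y_i^T through the conditional map."""
    d = X.shape[1]
    out = np.empty((traj[0].shape[1], d))
    for f in range(d):
        Xp = X.copy()
        Xp[i, f] += h
        Xm = X.copy()
        Xm[i, f] -= h
        out[:, f] = (
            conditional_replay(Xp, betas, i, traj, cfg)
            - conditional_replay(Xm, betas, i, traj, cfg)
        ) / (2 * h)
    return out


def exact_repulsive_sums(Y):
    """Dense O(n^2) repulsive force sums and normalizer."""
    U, Z, diffY = student_t_kernel(Y)
    return np.einsum("ij,ijp->ip", U * U, diffY), Z
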