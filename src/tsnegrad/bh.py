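"""Barnes-Hut quadtree approximation of the embedding-space sums.

t-SNE's gradient splits into an attractive term weighted by the sparse-ish P
and a repulsive term that sums the Student-t kernel over all pairs:

    F_rep,i = (1/Z) sum_j u_ij^2 (y_i - y_j),   Z = sum_{k != l} u_kl.

A quadtree groups distant points into cells; a cell of side ``w`` at distance
``r`` from the target is treated as ``N`` points at its center of mass
whenever ``w / r < theta``.  ``theta = 0`` never accepts a cell, reproducing
the exact sums.  The same traversal also accumulates the higher-order kernel
moments (sum u^2, sum u^2 delta, sum u^3 delta delta^T) that the gradient
tracker needs, so tracked Barnes-Hut runs reuse one tree per iteration.

2-D embeddings only (quadtree; an octree is out of scope).
"""
from __future__ import annotations

import numpy as np

from ._errors import ParameterError

_LEAF_SIZE = 1
_MAX_DEPTH = 48


class _Node:
    __slots__ = ("indices", "center", "half", "com", "count", "children", "is_leaf", "width")

    def __init__(self, indices, center, half):
        self.indices = indices
        self.center = center
        self.half = half  # half side length of the square cell
        self.width = 2.0 * half
        self.com = None
        self.count = len(indices)
        self.children = []
        self.is_leaf = True


def build_quadtree(Y: np.ndarray) -> _Node:
    """Build a square quadtree over 2-D points."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] != 2:
        raise ParameterError("Barnes-Hut tree requires a 2-D embedding")
    lo = Y.min(axis=0)
    hi = Y.max(axis=0)
    center = (lo + hi) / 2.0
    half = float(np.max(hi - lo) / 2.0) + 1e-9
    root = _Node(np.arange(Y.shape[0]), center, half)
    _subdivide(root, Y, 0)
    return root


def _subdivide(node: _Node, Y: np.ndarray, depth: int) -> None:
    pts = Y[node.indices]
    node.com = pts.mean(axis=0)
    if node.count <= _LEAF_SIZE or depth >= _MAX_DEPTH:
        return
    node.is_leaf = False
    cx, cy = node.center
    qh = node.half / 2.0
    east = pts[:, 0] >= cx
    north = pts[:, 1] >= cy
    for ex, ny in ((False, False), (False, True), (True, False), (True, True)):
        mask = (east == ex) & (north == ny)
        if not mask.any():
            continue
        child_center = np.array(
            [cx + (qh if ex else -qh), cy + (qh if ny else -qh)]
        )
        child = _Node(node.indices[mask], child_center, qh)
        node.children.append(child)
        _subdivide(child, Y, depth + 1)


def _accumulate(node: _Node, y: np.ndarray, i: int, theta: float, Y: np.ndarray, acc: dict) -> None:
    delta = y - node.com
    dist2 = float(delta @ delta)
    use_cell = (
        not node.is_leaf
        and theta > 0.0
        and dist2 > 0.0
        and (node.width * node.width) < (theta * theta) * dist2
    )
    if use_cell:
        # a cell never contains its own target when accepted: the target sits
        # inside the cell's bbox, making width/dist >= 1 > theta
        u = 1.0 / (1.0 + dist2)
        n_c = node.count
        acc["su"] += n_c * u
        u2 = u * u
        acc["su2"] += n_c * u2
        acc["su2d"] += (n_c * u2) * delta
        acc["su3dd"] += (n_c * u2 * u) * np.outer(delta, delta)
        return
    if node.is_leaf:
        for j in node.indices:
            if j == i:
                continue
            dj = y - Y[j]
            u = 1.0 / (1.0 + float(dj @ dj))
            acc["su"] += u
            u2 = u * u
            acc["su2"] += u2
            acc["su2d"] += u2 * dj
            acc["su3dd"] += (u2 * u) * np.outer(dj, dj)
        return
    for child in node.children:
        _accumulate(child, y, i, theta, Y, acc)


def tree_summaries(Y: np.ndarray, theta: float):
    """Per-point kernel moments and the Z estimate from one tree.

    Returns a dict with arrays over points i:
      su   : sum_j u_ij              (Z = su.sum())
      su2  : sum_j u_ij^2
      su2d : sum_j u_ij^2 (y_i - y_j)          shape (n, 2)
      su3dd: sum_j u_ij^3 (y_i-y_j)(y_i-y_j)^T shape (n, 2, 2)
    """
    Y = np.asarray(Y, dtype=float)
    if not (0.0 <= theta < 1.0):
        raise ParameterError("theta must lie in [0, 1)")
    root = build_quadtree(Y)
    n = Y.shape[0]
    su = np.zeros(n)
    su2 = np.zeros(n)
    su2d = np.zeros((n, 2))
    su3dd = np.zeros((n, 2, 2))
    for i in range(n):
        acc = {"su": 0.0, "su2": 0.0, "su2d": np.zeros(2), "su3dd": np.zeros((2, 2))}
        _accumulate(root, Y[i], i, theta, Y, acc)
        su[i] = acc["su"]
        su2[i] = acc["su2"]
        su2d[i] = acc["su2d"]
        su3dd[i] = acc["su3dd"]
    return {"su": su, "su2": su2, "su2d": su2d, "su3dd": su3dd, "Z": float(su.sum())}


def bh_forces(Y: np.ndarray, theta: float):
    """Approximate repulsive sums sum_j u^2 (y_i - y_j) and the Z estimate.

    The repulsive force is the returned array divided by Z.
    """
    s = tree_summaries(Y, theta)
    return s["su2d"], s["Z"]


def bh_step_quantities(Y: np.ndarray, P: np.ndarray, theta: float, exaggeration: float = 1.0):
    """Step quantities with the repulsive term and Z from the quadtree.

    The attractive (P-weighted) term is exact; Q is formed with the
    tree-estimated Z so the tracker sees one consistent normalizer.
    """
    from .tsne import StepQuantities, student_t_kernel

    U, _, diffY = student_t_kernel(Y)
    summ = tree_summaries(Y, theta)
    Z = summ["Z"]
    Phi = diffY * U[:, :, None]
    attract = np.einsum("ij,ijk->ik", exaggeration * P * U, diffY)
    repulse = summ["su2d"] / Z
    dY = 4.0 * (attract - repulse)
    return StepQuantities(
        Q=U / Z,
        Phi=Phi,
        dY=dY,
        Z=Z,
        U=U,
        diffY=diffY,
        exaggeration=exaggeration,
        bh_summaries=summ,
        P_eff=exaggeration * P,
    )
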