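"""Accuracy of the Barnes-Hut approximation to the repulsive t-SNE forces.

A quadtree treats distant groups of points as single masses at their center
of mass; the opening parameter theta trades speed for accuracy (theta = 0
reproduces the exact O(n^2) sums).
"""
import numpy as np

from tsnegrad.bh import bh_forces
from tsnegrad.tsne import student_t_kernel

rng = np.random.default_rng(0)
Y = np.vstack([rng.normal(size=(50, 2)) * 2 + c
               for c in [(0, 0), (20, 0), (0, 20), (15, 15)]])

U, Z, diffY = student_t_kernel(Y)
exact = np.einsum("ij,ijp->ip", U * U, diffY)

for theta in (0.0, 0.25, 0.5, 0.8):
    approx, Zb = bh_forces(Y, theta)
    err = np.linalg.norm(approx - exact, axis=1).max()
    rel = err / np.linalg.norm(exact, axis=1).max()
    print(f"theta={theta:4.2f}: max force error / max force = {rel:.2e}, "
          f"Z relative error = {abs(Zb - Z) / Z:.2e}")
# errors grow smoothly with theta; theta = 0 is exact to machine precision
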