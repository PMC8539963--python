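"""Reference direct Poisson solve, for validating the iterative solver.

This assembles the exact matrix form of the discrete Neumann Poisson
problem ``lap u = div G`` using the same forward-difference gradient and
backward-difference divergence as the evolution scheme, and solves it by
least squares (the Neumann Laplacian is singular: solutions are defined up
to a per-channel constant, removed here as the mean).

It exists as an independent cross-check for tests and the acceptance
script, not as a production solution path.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .solver import divergence
from .tensor import as_image, compute_gradient

__all__ = ["neumann_laplacian", "poisson_solve_direct"]


def _forward_diff_matrix(n: int) -> sp.csr_matrix:
    """1-D forward difference with a zero last row (replicate boundary)."""
    d = sp.diags([-np.ones(n), np.ones(n - 1)], [0, 1], format="lil")
    d[n - 1, n - 1] = 0.0
    return d.tocsr()


def neumann_laplacian(height: int, width: int) -> sp.csr_matrix:
    """Matrix of div(grad(.)) on an H x W grid, row-major flattening."""
    dx = sp.kron(sp.eye(height), _forward_diff_matrix(width), format="csr")
    dy = sp.kron(_forward_diff_matrix(height), sp.eye(width), format="csr")
    return (-(dx.T @ dx) - (dy.T @ dy)).tocsr()


def poisson_solve_direct(target: np.ndarray) -> np.ndarray:
    """Solve lap u = div(target) per channel; returns u with zero mean.

    ``target`` is an ``(H, W, 2, C)`` field.  The gauge freedom of the
    Neumann problem is fixed by removing the per-channel mean.
    """
    target = np.asarray(target, dtype=float)
    h, w, _, c = target.shape
    lap = neumann_laplacian(h, w).toarray()
    rhs = divergence(target).reshape(h * w, c)
    u = np.empty((h * w, c))
    for ch in range(c):
        sol, *_ = np.linalg.lstsq(lap, rhs[:, ch], rcond=None)
        u[:, ch] = sol - sol.mean()
    return u.reshape(h, w, c)


def laplacian_consistency_error(image: np.ndarray) -> float:
    """Max-abs difference between div(grad(u)) computed by the discrete
    operators and by the assembled matrix; a self-check utility."""
    u = as_image(image)
    h, w, c = u.shape
    op = divergence(compute_gradient(u))
    mat = (neumann_laplacian(h, w) @ u.reshape(h * w, c)).reshape(h, w, c)
    return float(np.max(np.abs(op - mat)))
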