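"""Shared restart-walk linear algebra.

Personalized propagation and random walk with restart are the same fixed
point, p = (1-r) W p + r p0 with a column-stochastic transition matrix W;
both public modules drive this one iteration kernel.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import scipy.sparse as sp


class WalkResult(NamedTuple):
    p: np.ndarray
    converged: bool
    n_iter: int


def column_stochastic(adjacency: sp.csr_matrix) -> sp.csr_matrix:
    """Column-normalize a symmetric adjacency; isolated nodes get a
    self-loop column so the matrix stays stochastic."""
    A = sp.csr_matrix(adjacency, dtype=np.float64)
    colsum = np.asarray(A.sum(axis=0)).ravel()
    isolated = np.nonzero(colsum == 0)[0]
    if isolated.size:
        A = A.tolil()
        for i in isolated:
            A[i, i] = 1.0
        A = A.tocsr()
        colsum = np.asarray(A.sum(axis=0)).ravel()
    inv = sp.diags(1.0 / colsum)
    return (A @ inv).tocsr()


def restart_walk(
    W: sp.csr_matrix,
    p0: np.ndarray,
    restart: float,
    tol: float,
    max_iter: int,
) -> WalkResult:
    """Iterate p <- (1-r) W p + r p0 to its fixed point.

    Stops when the L1 change drops below ``tol`` or the vector stagnates
    bit-for-bit (so sub-epsilon tolerances terminate at the numerical fixed
    point rather than spinning to ``max_iter``).  The fixed point is unique
    for restart > 0, so the result does not depend on the start vector.
    """
    if not 0.0 < restart <= 1.0:
        raise ValueError(f"restart probability must be in (0, 1], got {restart}")
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_new = (1.0 - restart) * (W @ p) + restart * p0
        delta = float(np.abs(p_new - p).sum())
        stagnated = np.array_equal(p_new, p)
        p = p_new
        if delta < tol or stagnated:
            return WalkResult(p, True, it)
    return WalkResult(p, False, max_iter)
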