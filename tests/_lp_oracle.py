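"""Independent brute-force LP oracle for minimum-spread fuzzy regression.

Enumerates vertices of the feasible polyhedron (all n-subsets of active
constraints) instead of calling an LP solver, so it shares no code path
with the implementation under test.  Only practical for tiny problems
(m <= ~6 observations, <= 3 design columns).
"""

from __future__ import annotations

import itertools

import numpy as np


def solve_min_spread_bruteforce(
    X: np.ndarray, y: np.ndarray, h: float = 0.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimise sum_j c_j * sum_i |x_ij| over free centers a and spreads c >= 0
    subject to  X a + (1-h)|X| c >= y  and  X a - (1-h)|X| c <= y.

    Returns (objective, centers, spreads) of the best feasible vertex.
    """
    m, k = X.shape
    absX = np.abs(X)
    weights = absX.sum(axis=0)
    n = 2 * k

    # all constraints in A z <= b form (coverage pairs + spread non-negativity)
    A = np.vstack(
        [
            np.hstack([-X, -(1.0 - h) * absX]),
            np.hstack([X, -(1.0 - h) * absX]),
            np.hstack([np.zeros((k, k)), -np.eye(k)]),
        ]
    )
    b = np.concatenate([-y, y, np.zeros(k)])
    cost = np.concatenate([np.zeros(k), weights])

    best = np.inf
    best_z: np.ndarray | None = None
    for rows in itertools.combinations(range(len(b)), n):
        Asub = A[list(rows)]
        if abs(np.linalg.det(Asub)) < 1e-9:
            continue
        z = np.linalg.solve(Asub, b[list(rows)])
        if np.all(A @ z <= b + 1e-8):
            val = float(cost @ z)
            if val < best:
                best, best_z = val, z
    if best_z is None:
        raise RuntimeError("no feasible vertex found")
    return best, best_z[:k], best_z[k:]
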