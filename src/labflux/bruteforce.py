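"""Exhaustive vertex-enumeration LP reference for tiny networks.

For a bounded, feasible LP ``max c.v`` s.t. ``S v = 0``, ``lb <= v <= ub``
the optimum is attained at a vertex of the polytope. Every vertex has a
"basic" index set B (|B| <= rank S, columns independent) with all other
variables pinned at a bound. Enumerating all column subsets and all
lower/upper combinations for the non-basic variables, solving the small
linear system for the basic part and keeping feasible candidates therefore
finds the exact optimum — independently of any iterative LP algorithm.

Tractable only for a handful of reactions; used to verify the FBA engine,
never to power it.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

__all__ = ["enumerate_lp_optimum"]


def enumerate_lp_optimum(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    tol: float = 1e-9,
) -> tuple[str, float]:
    """Return ``(status, objective)`` for max c.v, S v = 0, lb <= v <= ub.

    Requires finite bounds (the polytope is then bounded and the optimum, if
    the problem is feasible, sits on a vertex). Status is ``"optimal"`` or
    ``"infeasible"``.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("enumeration oracle requires finite bounds")
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    best: float | None = None
    indices = list(range(n))
    for size in range(rank + 1):
        for basic in combinations(indices, size):
            B = S[:, basic]
            if size and np.linalg.matrix_rank(B) < size:
                continue
            nonbasic = [j for j in indices if j not in basic]
            for choice in product((0, 1), repeat=len(nonbasic)):
                v = np.empty(n)
                for j, pick in zip(nonbasic, choice):
                    v[j] = ub[j] if pick else lb[j]
                rhs = -S[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(m)
                if size:
                    xb, residual, *_ = np.linalg.lstsq(B, rhs, rcond=None)
                    v[list(basic)] = xb
                if np.max(np.abs(S @ v)) > 1e-7:
                    continue
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                obj = float(c @ v)
                if best is None or obj > best:
                    best = obj
    if best is None:
        return "infeasible", float("nan")
    return "optimal", best
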