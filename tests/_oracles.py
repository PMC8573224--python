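"""Independent brute-force oracles for desk-scale checks.

These deliberately avoid HiGHS and OSQP (the production solve paths):
LP optima come from enumerating basic feasible solutions of the flux
polytope, MOMA optima from enumerating active sets of the KKT conditions
with dense linear algebra.  Only usable on small (<= ~15 reaction) models.
"""

from __future__ import annotations

import itertools

import numpy as np


def _dense(S) -> np.ndarray:
    return np.asarray(S.todense(), dtype=float) if hasattr(S, "todense") else np.asarray(S, float)


def enumerate_vertices(S, lb, ub, tol: float = 1e-7) -> list[np.ndarray]:
    """All basic feasible solutions of {S v = 0, lb <= v <= ub}.

    A bounded LP attains its optimum at one of these, so max/min over the
    list is an exact LP oracle.
    """
    S = _dense(S)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    vertices = []
    for fixed in itertools.combinations(range(n), n - r):
        free = [j for j in range(n) if j not in fixed]
        Sf = S[:, free]
        if np.linalg.matrix_rank(Sf) < r:
            continue
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            x_fixed = np.array(choice)
            rhs = -S[:, list(fixed)] @ x_fixed
            sol, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
            v = np.empty(n)
            v[list(fixed)] = x_fixed
            v[free] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(v)
    return vertices


def brute_force_lp(S, lb, ub, objective_index: int, direction: str = "max") -> float:
    """Exact LP optimum by vertex enumeration (bounded polytopes only)."""
    verts = enumerate_vertices(S, lb, ub)
    if not verts:
        raise ValueError("polytope is empty")
    values = [v[objective_index] for v in verts]
    return max(values) if direction == "max" else min(values)


def brute_force_moma(S, lb, ub, w, tol: float = 1e-7):
    """Exact MOMA optimum by KKT active-set enumeration.

    For the strictly convex QP min ||v - w||^2 over {S v = 0, lb <= v <= ub},
    the optimizer restricted to its own active set solves the corresponding
    equality-constrained projection; enumerating every active set and keeping
    the feasible candidate with least objective therefore recovers the exact
    optimum.  Bounds provably unreachable from w (farther than the objective
    at v = 0, which is feasible whenever lb <= 0 <= ub) are pruned.

    Returns (v_opt, squared_distance) or None when the polytope is empty.
    """
    S = _dense(S)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    w = np.asarray(w, float)
    m, n = S.shape

    # prune unreachable bound values to keep 3^n enumeration tractable
    cap = float(np.sum(w**2)) + 1.0 if np.all(lb <= 0) and np.all(ub >= 0) else np.inf
    options = []
    for j in range(n):
        opts: list[float | None] = [] if lb[j] == ub[j] else [None]
        for b in dict.fromkeys((lb[j], ub[j])):  # dedupe pinned bounds
            if np.isfinite(b) and (b - w[j]) ** 2 <= cap:
                opts.append(b)
        if not opts:
            opts = [None]
        options.append(opts)

    best = None
    for active in itertools.product(*options):
        fixed = [j for j, a in enumerate(active) if a is not None]
        free = [j for j, a in enumerate(active) if a is None]
        x_fixed = np.array([active[j] for j in fixed])
        if free:
            Sf = S[:, free]
            rhs = -(S[:, fixed] @ x_fixed) if fixed else np.zeros(m)
            # projection of w_free onto the affine subspace {Sf y = rhs}
            G = Sf @ Sf.T
            lam = np.linalg.pinv(G) @ (Sf @ w[free] - rhs)
            y = w[free] - Sf.T @ lam
            if np.max(np.abs(Sf @ y - rhs), initial=0.0) > tol:
                continue
        else:
            y = np.empty(0)
        v = np.empty(n)
        v[fixed] = x_fixed
        v[free] = y
        if np.max(np.abs(S @ v)) > tol:
            continue
        if not (np.all(v >= lb - tol) and np.all(v <= ub + tol)):
            continue
        obj = float(np.sum((v - w) ** 2))
        if best is None or obj < best[1]:
            best = (v, obj)
    return best


def truth_table_eval(rule_genes: list[str], rule_fn, deleted: set[str]) -> bool:
    """Evaluate a boolean rule by locating its row in the full truth table.

    ``rule_fn`` maps a dict {gene: bool} to a bool and is called for every
    one of the 2^k assignments, so any shortcut logic in the implementation
    under test is cross-checked against exhaustive enumeration.
    """
    table = {}
    for values in itertools.product([False, True], repeat=len(rule_genes)):
        assignment = dict(zip(rule_genes, values))
        table[values] = rule_fn(assignment)
    key = tuple(g not in deleted for g in rule_genes)
    return table[key]
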