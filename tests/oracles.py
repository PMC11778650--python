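"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's LP/solver code paths: the vertex
enumerator solves square linear systems directly, the GPR oracle evaluates
truth tables by substitution, and the dead-end oracle scans the dense S
matrix sign patterns row by row.
"""

from itertools import combinations, product

import numpy as np


def enumerate_vertices_objective(S, lb, ub, c, sense="max", tol=1e-9):
    """Optimal objective of  max/min c.v  s.t.  S v = 0, lb <= v <= ub,
    by enumerating basic solutions.

    For each choice of n - r nonbasic variables pinned at a bound (r =
    rank(S)), solves the remaining square system; feasible candidates are
    scored directly.  Exponential, only for tiny problems.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    best = None
    indices = range(n)
    for basic in combinations(indices, r):
        nonbasic = [j for j in indices if j not in basic]
        A = S[:, basic]
        if np.linalg.matrix_rank(A) < r:
            continue
        for bounds_choice in product(*[(lb[j], ub[j]) for j in nonbasic]):
            rhs = -S[:, nonbasic] @ np.asarray(bounds_choice) if nonbasic \
                else np.zeros(m)
            sol, residual, _, _ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.linalg.norm(S[:, basic] @ sol - rhs) > 1e-8:
                continue
            v = np.zeros(n)
            v[list(basic)] = sol
            for j, val in zip(nonbasic, bounds_choice):
                v[j] = val
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            score = float(c @ v)
            if best is None:
                best = score
            elif sense == "max":
                best = max(best, score)
            else:
                best = min(best, score)
    return best


def gpr_truth_table(expression, genes, deleted):
    """Plain recursive boolean evaluation used as the GPR oracle."""
    def ev(node):
        if isinstance(node, str):
            return node not in deleted
        op, children = node
        values = [ev(c) for c in children]
        return all(values) if op == "and" else any(values)

    if expression is None:
        return True
    return ev(expression)


def dead_ends_brute(S, lb, ub, met_ids):
    """Sign-pattern scan of the dense S matrix: a metabolite is a dead end
    iff, over reactions that can carry flux, it can only ever appear on one
    side of the mass balance."""
    S = np.asarray(S.todense() if hasattr(S, "todense") else S, dtype=float)
    out = []
    for i, met in enumerate(met_ids):
        can_produce = False
        can_consume = False
        touched = False
        for j in range(S.shape[1]):
            coef = S[i, j]
            if coef == 0:
                continue
            touched = True
            if ub[j] > 0:
                if coef > 0:
                    can_produce = True
                else:
                    can_consume = True
            if lb[j] < 0:
                if coef > 0:
                    can_consume = True
                else:
                    can_produce = True
        if touched and can_produce != can_consume:
            out.append(met)
    return sorted(out)
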