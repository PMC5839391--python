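"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: LP results are
checked against exhaustive vertex enumeration of the flux polytope, GPR
evaluation against a directly constructed expression tree, spanning
forests against enumeration of all spanning trees, and enrichment p-values
against an explicit hypergeometric tail sum.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# LP / polytope
# ---------------------------------------------------------------------------

def enumerate_vertices(
    A_eq: np.ndarray, b_eq: np.ndarray, bounds: Sequence[Tuple[float, float]], tol: float = 1e-8
) -> np.ndarray:
    """All vertices of {x : A_eq x = b_eq, lb <= x <= ub} (bounded polytope).

    A vertex has n - rank(A_eq) coordinates at a bound; enumerate every
    choice of fixed coordinates and bound side, solve for the rest, keep
    feasible unique solutions.
    """
    A_eq = np.asarray(A_eq, dtype=float)
    b_eq = np.asarray(b_eq, dtype=float)
    m, n = A_eq.shape
    r = int(np.linalg.matrix_rank(A_eq))
    lbs = np.array([b[0] for b in bounds])
    ubs = np.array([b[1] for b in bounds])
    verts: List[np.ndarray] = []
    for free in itertools.combinations(range(n), r):
        fixed = [j for j in range(n) if j not in free]
        A_f = A_eq[:, free]
        if np.linalg.matrix_rank(A_f) < r:
            continue
        for sides in itertools.product((0, 1), repeat=len(fixed)):
            x = np.empty(n)
            for j, s in zip(fixed, sides):
                x[j] = lbs[j] if s == 0 else ubs[j]
            rhs = b_eq - A_eq[:, fixed] @ x[fixed]
            sol, res, rank, _ = np.linalg.lstsq(A_f, rhs, rcond=None)
            x[list(free)] = sol
            if np.max(np.abs(A_eq @ x - b_eq)) > tol:
                continue
            if (x < lbs - tol).any() or (x > ubs + tol).any():
                continue
            if not any(np.max(np.abs(x - v)) < 1e-6 for v in verts):
                verts.append(x)
    return np.array(verts)


def model_vertices(model, fix_objective_at: Optional[float] = None) -> np.ndarray:
    """Vertices of a model's flux polytope, optionally on the optimal face."""
    S = model.stoichiometric_matrix()
    b = np.zeros(S.shape[0])
    if fix_objective_at is not None:
        row = np.zeros(len(model.reactions))
        row[model.reaction_ids.index(model.objective)] = 1.0
        S = np.vstack([S, row[None, :]])
        b = np.append(b, fix_objective_at)
    return enumerate_vertices(S, b, model.bounds())


def lp_max_by_vertices(model, objective_id: Optional[str] = None) -> float:
    verts = model_vertices(model)
    j = model.reaction_ids.index(objective_id or model.objective)
    return float(verts[:, j].max())


# ---------------------------------------------------------------------------
# GPR
# ---------------------------------------------------------------------------

def all_gpr_trees(max_ops: int, genes: List[str]):
    """Every binary AND/OR tree with up to ``max_ops`` operators; leaves take
    distinct genes left to right.  Yields (n_leaves, nested-tuple tree)."""

    def shapes(k: int):
        if k == 0:
            yield "leaf"
            return
        for left_k in range(k):
            for op in ("and", "or"):
                for l in shapes(left_k):
                    for r in shapes(k - 1 - left_k):
                        yield (op, l, r)

    def attach(shape, it):
        if shape == "leaf":
            return next(it)
        op, l, r = shape
        return (op, attach(l, it), attach(r, it))

    for k in range(max_ops + 1):
        for shape in shapes(k):
            it = iter(genes)
            yield k + 1, attach(shape, it)


def tree_to_string(tree) -> str:
    if isinstance(tree, str):
        return tree
    op, l, r = tree
    return f"({tree_to_string(l)}) {op} ({tree_to_string(r)})"


def eval_tree(tree, values: Dict[str, float]) -> Optional[float]:
    if isinstance(tree, str):
        return values.get(tree)
    op, l, r = tree
    a, b = eval_tree(l, values), eval_tree(r, values)
    defined = [v for v in (a, b) if v is not None]
    if not defined:
        return None
    if len(defined) == 1:
        return defined[0]
    return a + b if op == "or" else min(a, b)


# ---------------------------------------------------------------------------
# spanning trees
# ---------------------------------------------------------------------------

def max_spanning_tree_weight(nodes: Sequence[str], weights: Dict[Tuple[str, str], float]) -> float:
    """Exhaustive maximum spanning tree total weight (n <= 7)."""
    import networkx as nx

    all_edges = sorted(weights)
    n = len(nodes)
    best = -np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(subset)
        if nx.is_connected(g):
            best = max(best, sum(weights[e] for e in subset))
    return best


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------

def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), by direct summation."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


# ---------------------------------------------------------------------------
# median-effect grid search
# ---------------------------------------------------------------------------

def grid_search_median_effect(doses, viability, m_range=(0.2, 6.0), dm_range=(0.5, 200.0)):
    """Two-stage grid minimizer of the log-odds SSE over (m, Dm)."""
    doses = np.asarray(doses, float)
    viability = np.asarray(viability, float)
    fa = 1 - viability / 100.0
    use = (doses > 0) & (fa > 0) & (fa < 1)
    x, y = np.log(doses[use]), np.log(fa[use] / (1 - fa[use]))

    def sse(m, dm):
        return float(((y - m * (x - np.log(dm))) ** 2).sum())

    best = (np.inf, None, None)
    ms = np.linspace(*m_range, 241)
    dms = np.geomspace(*dm_range, 241)
    for m in ms:
        for dm in dms:
            s = sse(m, dm)
            if s < best[0]:
                best = (s, m, dm)
    _, m0, dm0 = best
    ms = np.linspace(m0 * 0.9, m0 * 1.1, 201)
    dms = np.geomspace(dm0 * 0.9, dm0 * 1.1, 201)
    for m in ms:
        for dm in dms:
            s = sse(m, dm)
            if s < best[0]:
                best = (s, m, dm)
    return best[1], best[2]
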