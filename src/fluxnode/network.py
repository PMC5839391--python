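"""Correlation-tree functional network and node activities.

The graphical model over proteins is the treewidth-1 decomposable MLE: a
maximum-weight spanning forest on absolute Pearson correlation, built from
normalized log2 intensities.  Cutting the weakest tree edges splits the
forest into branches; each branch is labeled with its most over-represented
annotation term (one-sided hypergeometric test), and the activity of a
labeled branch under a perturbation is the mean treated-minus-control delta
of the branch proteins carrying that label.  Exhaustive-subset ordinary
least squares relates activities (or pathway flux activities) to drug
response.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .prep import DeltaTable, ExpressionMatrix

__all__ = [
    "FunctionalNetwork",
    "RegressionResult",
    "build_tree",
    "split_branches",
    "label_branches",
    "node_activities",
    "fit_response_model",
]


@dataclass
class FunctionalNetwork:
    nodes: List[str]
    edges: List[Tuple[str, str, float]]        # spanning-forest edges (u < v, weight)
    branches: List[FrozenSet[str]]
    labels: Dict[int, Optional[str]] = field(default_factory=dict)
    enrichment: Optional[pd.DataFrame] = None  # branch, term, k, K, n, N, p, q
    annotation: Optional[Dict[str, Set[str]]] = None

    @property
    def labeled_branches(self) -> Dict[int, str]:
        return {i: t for i, t in self.labels.items() if t is not None}

    def to_edgelist(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["source", "target", "weight"])


def _components(nodes: Sequence[str], edges: Sequence[Tuple[str, str, float]]) -> List[FrozenSet[str]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((u, v) for u, v, _ in edges)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: min(c))


def build_tree(x: ExpressionMatrix) -> FunctionalNetwork:
    """Maximum-|Pearson ρ| spanning forest over proteins.

    Kruskal with a deterministic tie-break (higher weight first, then
    lexicographic edge id).  Zero-variance proteins have no defined
    correlation and are excluded with a warning.
    """
    if x.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    vals = x.intensities
    sd = vals.std(axis=1, ddof=0)
    if (sd == 0).any():
        dropped = list(vals.index[sd == 0])
        warnings.warn(f"excluding {len(dropped)} constant protein(s): {dropped[:5]}")
        vals = vals.loc[sd > 0]
    nodes = sorted(vals.index)
    vals = vals.loc[nodes]
    corr = np.abs(np.corrcoef(vals.values))
    np.fill_diagonal(corr, 0.0)

    n = len(nodes)
    order = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda ij: (-corr[ij], nodes[ij[0]], nodes[ij[1]]),
    )
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: List[Tuple[str, str, float]] = []
    for i, j in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((nodes[i], nodes[j], float(corr[i, j])))
            if len(edges) == n - 1:
                break
    return FunctionalNetwork(nodes=nodes, edges=edges, branches=_components(nodes, edges))


def split_branches(net: FunctionalNetwork, n_branches: int) -> FunctionalNetwork:
    """Cut the n_branches − 1 lowest-weight forest edges; the connected
    components that remain are the branches."""
    if not 1 <= n_branches <= len(net.nodes):
        raise ValueError("n_branches must be between 1 and the node count")
    by_weight = sorted(net.edges, key=lambda e: (e[2], e[0], e[1]))
    cut = set((u, v) for u, v, _ in by_weight[: n_branches - 1])
    kept = [e for e in net.edges if (e[0], e[1]) not in cut]
    return FunctionalNetwork(
        nodes=list(net.nodes), edges=kept, branches=_components(net.nodes, kept)
    )


def default_branch_count(n_proteins: int) -> int:
    """Branch granularity mirroring ~36 branches per ~4000 proteins."""
    return max(1, -(-n_proteins // 115))


def label_branches(
    net: FunctionalNetwork, annotation: Mapping[str, Set[str]], alpha: float = 0.05
) -> FunctionalNetwork:
    """Assign each branch its most significantly over-represented term.

    One-sided hypergeometric tail P[X >= k] against the background of all
    network nodes; the smallest-p term wins if p < alpha (ties: larger
    in-branch count, then lexicographic term), else the branch is "none".
    Benjamini-Hochberg q-values over all branch × term tests are reported
    alongside the raw p-values.
    """
    background = set(net.nodes)
    N = len(background)
    rows = []
    labels: Dict[int, Optional[str]] = {}
    for bi, branch in enumerate(net.branches):
        n = len(branch)
        best: Optional[Tuple[float, int, str]] = None
        for term in sorted(annotation):
            members = set(annotation[term]) & background
            K = len(members)
            if K == 0:
                continue
            k = len(branch & members)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append({"branch": bi, "term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
            if k > 0:
                cand = (p, -k, term)
                if best is None or cand < best:
                    best = cand
        labels[bi] = best[2] if best is not None and best[0] < alpha else None

    enr = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["branch", "term", "k", "K", "n", "N", "p"])
    if len(enr):
        enr["q"] = multipletests(enr["p"].values, method="fdr_bh")[1]
    return FunctionalNetwork(
        nodes=list(net.nodes),
        edges=list(net.edges),
        branches=list(net.branches),
        labels=labels,
        enrichment=enr,
        annotation={t: set(s) for t, s in annotation.items()},
    )


def node_activities(net: FunctionalNetwork, d: DeltaTable) -> pd.DataFrame:
    """Functional-node activity: mean delta over the branch proteins that
    carry the branch's label, per (cell line, drug) pair."""
    if net.annotation is None:
        raise ValueError("network is not labeled; call label_branches first")
    rows = {}
    for bi, term in net.labeled_branches.items():
        members = sorted(net.branches[bi] & net.annotation[term])
        members = [p for p in members if p in d.deltas.index]
        if not members:
            raise ValueError(f"branch {bi} labeled {term!r} has no proteins in the delta table")
        rows[f"n{bi}:{term}"] = d.deltas.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T


def read_gmt(path) -> Dict[str, Set[str]]:
    """GMT annotation: term <tab> description <tab> protein ids."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(p for p in parts[2:] if p)
    return out


def write_gmt(annotation: Mapping[str, Set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            fh.write("\t".join([term, description] + sorted(annotation[term])) + "\n")


def write_graphml(net: FunctionalNetwork, path) -> None:
    import networkx as nx

    g = nx.Graph()
    branch_of = {p: bi for bi, b in enumerate(net.branches) for p in b}
    for node in net.nodes:
        bi = branch_of[node]
        g.add_node(node, branch=bi, label=net.labels.get(bi) or "none")
    for u, v, w in net.edges:
        g.add_edge(u, v, weight=w)
    nx.write_graphml(g, path)


@dataclass
class RegressionResult:
    predictors: Tuple[str, ...]
    coefficients: Dict[str, float]  # includes "intercept"
    r2: float
    adjusted_r2: float
    n_obs: int


def fit_response_model(
    features: pd.DataFrame, response: pd.Series, max_terms: int = 2
) -> RegressionResult:
    """Exhaustive best-subset OLS maximizing adjusted R².

    ``features`` is observations × candidate predictors; subsets up to
    ``max_terms`` are fit by least squares and ranked by
    adj R² = 1 − (1 − R²)(n − 1)/(n − k − 1).  Rank-deficient (collinear)
    subsets are skipped with a warning.
    """
    features = features.loc[response.index]
    y = response.values.astype(float)
    n = len(y)
    best: Optional[RegressionResult] = None
    for k in range(1, max_terms + 1):
        if n < k + 2:
            break
        for subset in itertools.combinations(sorted(features.columns), k):
            X = np.column_stack([np.ones(n), features[list(subset)].values])
            if np.linalg.matrix_rank(X) < k + 1:
                warnings.warn(f"collinear subset skipped: {subset}")
                continue
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            ss_res = float(resid @ resid)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
            if best is None or adj > best.adjusted_r2:
                coeffs = {"intercept": float(beta[0])}
                coeffs.update({name: float(b) for name, b in zip(subset, beta[1:])})
                best = RegressionResult(
                    predictors=subset, coefficients=coeffs, r2=r2, adjusted_r2=adj, n_obs=n
                )
    if best is None:
        raise ValueError("no admissible predictor subset (too few observations?)")
    return best
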