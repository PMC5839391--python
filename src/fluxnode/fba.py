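"""Linear-programming core: FBA, FVA, maximum-|v| solution, optimal-face sampling.

All solves go through scipy's HiGHS interface with fixed tolerances
(feasibility 1e-9, optimality 1e-7), so repeated runs are deterministic.
Degeneracy of the optimal face — many flux vectors sharing the optimal
growth rate — is handled explicitly: :func:`max_l1_solution` picks the
vertex with the largest total flux (every measured enzyme carrying flux
where possible) and :func:`sample_optimal_face` draws vertices of the face
under random linear objectives as a Monte-Carlo picture of the whole
solution landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = ["FluxSolution", "FVARange", "fba", "fva", "max_l1_solution", "sample_optimal_face"]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-7
#: slack used when fixing the objective at its optimum in follow-up solves
OBJECTIVE_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    fluxes: Dict[str, float]
    objective_value: float
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def vector(self, reaction_ids: List[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])


@dataclass
class FVARange:
    minimum: Dict[str, float]
    maximum: Dict[str, float]
    fraction: float

    def width(self, rid: str) -> float:
        return self.maximum[rid] - self.minimum[rid]


def _linprog(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": OPTIMALITY_TOL,
        },
    )


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize biomass flux subject to S·v = 0 and the flux bounds."""
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_ids.index(model.objective)] = -1.0  # linprog minimizes
    res = _linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=model.bounds())
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(fluxes={}, objective_value=float("nan"), status=status)
    return FluxSolution(
        fluxes=dict(zip(model.reaction_ids, res.x)),
        objective_value=float(-res.fun),
        status="optimal",
    )


def _optimum_or_raise(model: MetabolicModel) -> float:
    sol = fba(model)
    if not sol.optimal:
        raise RuntimeError(f"FBA on {model.id!r} is {sol.status}")
    return sol.objective_value


def fva(model: MetabolicModel, fraction: float = 1.0) -> FVARange:
    """Per-reaction flux minimum/maximum with biomass held at ``fraction``·μ*."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mu = _optimum_or_raise(model)
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    obj_row = np.zeros(n)
    obj_row[model.reaction_ids.index(model.objective)] = -1.0
    # biomass >= fraction * mu  (tiny slack so the optimum itself is feasible)
    A_ub = obj_row[None, :]
    b_ub = np.array([-(fraction * mu - FEASIBILITY_TOL)])
    bnds = model.bounds()
    b_eq = np.zeros(S.shape[0])

    vmin, vmax = {}, {}
    for j, rid in enumerate(model.reaction_ids):
        c = np.zeros(n)
        c[j] = 1.0
        lo = _linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq, bounds=bnds)
        hi = _linprog(-c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq, bounds=bnds)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid!r} failed")
        vmin[rid] = float(lo.fun)
        vmax[rid] = float(-hi.fun)
    return FVARange(minimum=vmin, maximum=vmax, fraction=fraction)


def max_l1_solution(model: MetabolicModel) -> FluxSolution:
    """Optimal-face vertex maximizing total flux Σ|v|.

    Flux splitting v = v⁺ − v⁻ (v± ≥ 0, capped by the model bounds) turns
    Σ|v| into the linear Σ(v⁺ + v⁻); biomass is fixed at its optimum.  This
    solution "uses" every enzyme that can carry flux, matching the premise
    that a measured protein is a protein the cell employs.
    """
    mu = _optimum_or_raise(model)
    S = model.stoichiometric_matrix()
    m, n = S.shape
    # variables: [v+ (n), v- (n)]
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    obj_row = np.zeros(2 * n)
    j_obj = model.reaction_ids.index(model.objective)
    obj_row[j_obj] = 1.0
    obj_row[n + j_obj] = -1.0
    A_eq = np.vstack([A_eq, obj_row])
    b_eq = np.append(b_eq, mu)

    bnds = []
    capped = False
    for lb, ub in model.bounds():
        if not np.isfinite(ub) or not np.isfinite(lb):
            capped = True
        bnds.append((0.0, max(ub, 0.0) if np.isfinite(ub) else None))
    for lb, ub in model.bounds():
        bnds.append((0.0, max(-lb, 0.0) if np.isfinite(lb) else None))
    if capped:
        warnings.warn("unbounded |v| possible through open bounds; relying on finite caps only")

    c = -np.ones(2 * n)  # maximize total split flux
    res = _linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bnds)
    if res.status != 0:
        return FluxSolution(fluxes={}, objective_value=float("nan"), status=_STATUS.get(res.status, "failed"))
    v = res.x[:n] - res.x[n:]
    return FluxSolution(fluxes=dict(zip(model.reaction_ids, v)), objective_value=mu, status="optimal")


def sample_optimal_face(model: MetabolicModel, n: int, seed: int) -> List[FluxSolution]:
    """Monte-Carlo vertices of the optimal face.

    Each sample maximizes a random direction (uniform on the unit sphere,
    seeded) over the flux polytope with biomass pinned to μ*, so every draw
    is itself optimal in biomass and an extreme representative of the
    alternate-optima landscape.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mu = _optimum_or_raise(model)
    S = model.stoichiometric_matrix()
    nrxn = len(model.reactions)
    obj_row = np.zeros(nrxn)
    obj_row[model.reaction_ids.index(model.objective)] = 1.0
    A_eq = np.vstack([S, obj_row[None, :]])
    b_eq = np.append(np.zeros(S.shape[0]), mu)
    bnds = model.bounds()

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        d = rng.standard_normal(nrxn)
        d /= np.linalg.norm(d)
        res = _linprog(-d, A_eq=A_eq, b_eq=b_eq, bounds=bnds)
        if res.status != 0:
            raise RuntimeError("optimal-face sample infeasible")
        out.append(
            FluxSolution(fluxes=dict(zip(model.reaction_ids, res.x)), objective_value=mu, status="optimal")
        )
    return out
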