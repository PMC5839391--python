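"""Pathway flux activities and treatment-responsive reaction detection.

Flux activity summarizes a whole pathway (model subsystem) as the sum of
absolute fluxes of its reactions.  Responsive reactions are those whose
flux moves, between control and treated conditions, by more than a set
fraction (default 95%) of the union of the two conditions' FVA ranges; a
Monte-Carlo consistency check asks how often alternate optimal solutions
reproduce each flagged change.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import pandas as pd

from .fba import FluxSolution, FVARange
from .model import MetabolicModel

__all__ = ["flux_activities", "flux_activity_table", "detect_changes", "consistency_check"]

UNASSIGNED = "unassigned"


def flux_activities(solution: FluxSolution, model: MetabolicModel) -> pd.Series:
    """Per-pathway activity Σ_r |v_r| over reactions of each subsystem.

    Absolute values keep opposing reversible fluxes from cancelling.  Every
    model subsystem appears; reactions without one pool under 'unassigned'.
    """
    if not solution.optimal:
        raise ValueError("flux activities need an optimal solution")
    acc: Dict[str, float] = {}
    for r in model.reactions:
        acc.setdefault(r.subsystem or UNASSIGNED, 0.0)
        acc[r.subsystem or UNASSIGNED] += abs(solution.fluxes[r.id])
    return pd.Series(acc).sort_index()


def flux_activity_table(
    solutions: Dict[str, FluxSolution], model: MetabolicModel, control: str = "control"
) -> pd.DataFrame:
    """Activities per condition, with treated − control delta columns."""
    tab = pd.DataFrame({cond: flux_activities(sol, model) for cond, sol in solutions.items()})
    if control in tab.columns:
        for cond in tab.columns:
            if cond != control:
                tab[f"delta_{cond}"] = tab[cond] - tab[control]
    return tab


def detect_changes(
    ctrl: FluxSolution,
    trt: FluxSolution,
    fva_ctrl: FVARange,
    fva_trt: FVARange,
    frac: float = 0.95,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Flag reactions whose control→treated flux change exceeds ``frac`` of
    the union FVA range of the two conditions.

    Zero-width ranges (reactions pinned to one value in both conditions)
    are never flagged.  Returns a per-reaction report with columns
    control_flux, treated_flux, range_width, change_fraction, flagged.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    rxns = sorted(ctrl.fluxes)
    for other in (trt.fluxes, fva_ctrl.minimum, fva_trt.minimum):
        if sorted(other) != rxns:
            raise ValueError("reaction sets of the two conditions do not match")
    rows = []
    for rid in rxns:
        lo = min(fva_ctrl.minimum[rid], fva_trt.minimum[rid])
        hi = max(fva_ctrl.maximum[rid], fva_trt.maximum[rid])
        width = hi - lo
        delta = abs(trt.fluxes[rid] - ctrl.fluxes[rid])
        fraction = delta / width if width > tol else 0.0
        rows.append(
            {
                "reaction": rid,
                "control_flux": ctrl.fluxes[rid],
                "treated_flux": trt.fluxes[rid],
                "range_width": width,
                "change_fraction": fraction,
                "flagged": bool(width > tol and fraction > frac),
            }
        )
    return pd.DataFrame(rows).set_index("reaction")


def consistency_check(
    report: pd.DataFrame,
    samples_ctrl: Sequence[FluxSolution],
    samples_trt: Sequence[FluxSolution],
    frac: float = 0.95,
) -> pd.Series:
    """Monte-Carlo support for each flagged reaction.

    For every flagged reaction, the fraction of sampled solution pairs
    whose change also exceeds ``frac`` of that reaction's union FVA range.
    Equal-length sample lists are paired by index; otherwise all pairs are
    compared.  Zero-support reactions are reported, not dropped.
    """
    if len(samples_ctrl) == 0 or len(samples_trt) == 0:
        raise ValueError("need at least one sample per condition")
    if len(samples_ctrl) == len(samples_trt):
        pairs: List = list(zip(samples_ctrl, samples_trt))
    else:
        pairs = [(c, t) for c in samples_ctrl for t in samples_trt]
    flagged = report.index[report["flagged"]]
    out = {}
    for rid in flagged:
        width = report.loc[rid, "range_width"]
        hits = sum(1 for c, t in pairs if abs(t.fluxes[rid] - c.fluxes[rid]) > frac * width)
        out[rid] = hits / len(pairs)
    return pd.Series(out, dtype=float)
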