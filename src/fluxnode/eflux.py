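"""E-flux integration of protein abundance into flux bounds.

Each reaction with a GPR rule gets a raw score a_j from the rule evaluated
against per-gene protein intensities (OR = sum, AND = min).  Raw scores of
one sample are min-max rescaled to [0, 1] — the Uniform(min, max) CDF — and
the normalized score a_j' replaces the reaction's bounds: irreversible
reactions get [0, a_j'], reversible ones [-a_j', a_j'].  Reactions without a
rule, or whose rule is entirely unmeasured, keep their original bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

from .gpr import evaluate_gpr, parse_gpr
from .model import MetabolicModel

__all__ = ["GPRScore", "score_reactions", "normalize_scores", "apply_eflux"]


@dataclass(frozen=True)
class GPRScore:
    reaction_id: str
    raw: float
    normalized: Optional[float] = None  # in [0, 1] once normalized


def score_reactions(model: MetabolicModel, expression: Mapping[str, float]) -> List[GPRScore]:
    """Evaluate every GPR-bearing reaction against one sample's expression.

    Linear-scale (untransformed) intensities are expected: the OR-sum
    semantics add isozyme abundances, which log-scale values would distort.
    Reactions whose rule has no measured gene are omitted (undefined score).
    """
    scores = []
    for r in model.reactions:
        if r.gpr is None:
            continue
        v = evaluate_gpr(parse_gpr(r.gpr), expression)
        if v is not None:
            scores.append(GPRScore(reaction_id=r.id, raw=v))
    return scores


def normalize_scores(scores: List[GPRScore]) -> List[GPRScore]:
    """Min-max rescale raw scores of one sample to [0, 1].

    With all raw values equal there is no dynamic range; every score maps to
    1 (fully open bounds) and a warning is emitted.
    """
    if not scores:
        return []
    raw = [s.raw for s in scores]
    lo, hi = min(raw), max(raw)
    if hi == lo:
        warnings.warn("all raw GPR scores equal; normalizing every score to 1.0")
        return [GPRScore(s.reaction_id, s.raw, 1.0) for s in scores]
    return [GPRScore(s.reaction_id, s.raw, (s.raw - lo) / (hi - lo)) for s in scores]


def apply_eflux(model: MetabolicModel, scores: List[GPRScore]) -> MetabolicModel:
    """Return a new model with E-flux bounds from normalized scores.

    Scored irreversible reactions get bounds [0, a'], scored reversible ones
    [-a', a']; unscored reactions keep their bounds.  The input model is not
    modified.
    """
    by_rxn: Dict[str, float] = {}
    for s in scores:
        if s.normalized is None:
            raise ValueError(f"score for {s.reaction_id!r} is not normalized")
        if s.reaction_id in by_rxn:
            raise ValueError(f"duplicate score for reaction {s.reaction_id!r}")
        by_rxn[s.reaction_id] = s.normalized

    unknown = set(by_rxn) - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"scores reference unknown reactions: {sorted(unknown)}")

    out = model.copy()
    for rid, a in by_rxn.items():
        r = out.reaction(rid)
        if r.reversible:
            out = out.with_bounds(rid, -a, a)
        else:
            out = out.with_bounds(rid, 0.0, a)
    return out
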