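"""Constraint-based metabolic model container and its native JSON dialect.

The model is the usual stoichiometric object: metabolites, reactions with
stoichiometry and flux bounds, optional GPR rule and subsystem (pathway)
label per reaction, and one biomass reaction as the growth objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .gpr import parse_gpr

__all__ = ["Reaction", "MetabolicModel", "ModelValidationError"]


class ModelValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Dict[str, float]  # metabolite -> coefficient (<0 consumed)
    lower_bound: float
    upper_bound: float
    gpr: Optional[str] = None
    subsystem: Optional[str] = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions exchange mass with the environment."""
        return all(c > 0 for c in self.stoichiometry.values()) or all(
            c < 0 for c in self.stoichiometry.values()
        )


@dataclass
class MetabolicModel:
    id: str
    metabolites: List[str]
    reactions: List[Reaction]
    objective: str  # biomass reaction id
    _rxn_index: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- access ---------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S, one row per metabolite, one column per reaction."""
        midx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[midx[m], j] = c
        return S

    def bounds(self) -> List[tuple]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    # -- editing --------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            objective=self.objective,
        )

    def with_bounds(self, rid: str, lower: float, upper: float) -> "MetabolicModel":
        """New model with one reaction's bounds replaced (input unmodified)."""
        out = self.copy()
        i = out._rxn_index[rid]
        out.reactions[i] = replace(out.reactions[i], lower_bound=lower, upper_bound=upper)
        return out

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.objective not in self._rxn_index:
            raise ModelValidationError(f"objective reaction {self.objective!r} not in model")
        mets = set(self.metabolites)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(f"{r.id}: lower bound exceeds upper bound")
            if not r.stoichiometry:
                raise ModelValidationError(f"{r.id}: empty stoichiometry")
            unknown = set(r.stoichiometry) - mets
            if unknown:
                raise ModelValidationError(f"{r.id}: unknown metabolites {sorted(unknown)}")
            if r.gpr is not None:
                parse_gpr(r.gpr)  # raises on malformed rule
        if len(set(self.reaction_ids)) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")

    # -- native JSON dialect -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "metabolites": list(self.metabolites),
            "objective": self.objective,
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": {m: r.stoichiometry[m] for m in sorted(r.stoichiometry)},
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gpr": r.gpr,
                    "subsystem": r.subsystem,
                }
                for r in self.reactions
            ],
        }

    def to_json(self) -> str:
        # sorted keys + fixed separators => byte-stable serialization
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        return cls(
            id=d["id"],
            metabolites=list(d["metabolites"]),
            reactions=[
                Reaction(
                    id=r["id"],
                    stoichiometry=dict(r["stoichiometry"]),
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    gpr=r.get("gpr"),
                    subsystem=r.get("subsystem"),
                )
                for r in d["reactions"]
            ],
            objective=d["objective"],
        )

    @classmethod
    def from_json(cls, text: str) -> "MetabolicModel":
        return cls.from_dict(json.loads(text))

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load_json(cls, path) -> "MetabolicModel":
        with open(path) as fh:
            return cls.from_json(fh.read())
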