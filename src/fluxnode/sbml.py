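"""SBML Level 3 + FBC import/export, backed by cobrapy/libsbml.

Conversion to and from the package's own :class:`~fluxnode.model.MetabolicModel`
keeps bounds, GPR association strings, subsystem labels and the (single)
biomass objective.
"""

from __future__ import annotations

from .model import MetabolicModel, Reaction

__all__ = ["to_cobra", "from_cobra", "write_sbml", "read_sbml"]


def to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    cm.add_metabolites([cobra.Metabolite(m, compartment="c") for m in model.metabolites])
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        if r.subsystem:
            cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    cm.objective = cm.reactions.get_by_id(model.objective)
    return cm


def from_cobra(cm) -> MetabolicModel:
    objective = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    if objective is None:
        raise ValueError("cobra model has no objective reaction")
    model = MetabolicModel(
        id=cm.id or "model",
        metabolites=[m.id for m in cm.metabolites],
        reactions=[
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=r.gene_reaction_rule or None,
                subsystem=r.subsystem or None,
            )
            for r in cm.reactions
        ],
        objective=objective,
    )
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path) -> None:
    import cobra

    cobra.io.write_sbml_model(to_cobra(model), str(path))


def read_sbml(path) -> MetabolicModel:
    import cobra

    return from_cobra(cobra.io.read_sbml_model(str(path)))
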