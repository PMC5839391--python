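"""Synthetic data with known ground truth.

Generators for (1) toy constraint-based metabolic models shaped like a
miniature genome-scale reconstruction — substrate uptake, a linear
bottleneck chain, a block of parallel (degenerate) routes, a biomass sink,
GPR rules and subsystem labels; (2) MaxQuant-style label-free proteomics
experiments with planted per-term log2 effects, replicate columns, missing
values and peptide-count metadata; (3) term → protein annotations; and
(4) median-effect viability tables.  Every generator takes an explicit
seed and reproduces byte-identical output for the same spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .dose import ViabilityTable
from .model import MetabolicModel, Reaction
from .prep import ExpressionMatrix

__all__ = [
    "ToyModelSpec",
    "SyntheticExperimentSpec",
    "make_toy_model",
    "make_annotation",
    "make_expression",
    "make_viability",
    "delta_standard_error",
]


# ---------------------------------------------------------------------------
# toy metabolic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelSpec:
    n_linear_reactions: int = 3
    n_parallel_branches: int = 2
    uptake_bound: float = 10.0
    genes_per_reaction: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_linear_reactions, self.n_parallel_branches, self.genes_per_reaction) < 1:
            raise ValueError("counts must be >= 1")
        if self.uptake_bound < 0:
            raise ValueError("uptake_bound must be >= 0")


def _gpr_for(genes: List[str], rng: np.random.Generator) -> str:
    """Fixed grammar: single gene, AND pair, or OR pair."""
    if len(genes) == 1:
        return genes[0]
    op = "and" if rng.random() < 0.5 else "or"
    return f" {op} ".join(genes)


def make_toy_model(spec: ToyModelSpec) -> MetabolicModel:
    """Uptake → linear chain → parallel block → biomass sink.

    Fluxes are dimensionless; the single bottleneck is the uptake bound, so
    the FBA optimum equals ``uptake_bound``.  Every internal reaction gets a
    GPR over ``genes_per_reaction`` fresh genes; subsystems label the blocks.
    """
    rng = np.random.default_rng(spec.seed)
    mets: List[str] = []
    rxns: List[Reaction] = []
    gene_counter = 0

    def fresh_genes(k: int) -> List[str]:
        nonlocal gene_counter
        out = [f"g{gene_counter + i + 1}" for i in range(k)]
        gene_counter += k
        return out

    mets.append("M0")
    rxns.append(
        Reaction("EX_upt", {"M0": 1.0}, 0.0, spec.uptake_bound, gpr=None, subsystem="exchange")
    )
    prev = "M0"
    for i in range(1, spec.n_linear_reactions + 1):
        m = f"M{i}"
        mets.append(m)
        rxns.append(
            Reaction(
                f"CHAIN_{i}",
                {prev: -1.0, m: 1.0},
                0.0,
                1000.0,
                gpr=_gpr_for(fresh_genes(spec.genes_per_reaction), rng),
                subsystem="linear chain",
            )
        )
        prev = m
    mets.append("MP")
    for j in range(1, spec.n_parallel_branches + 1):
        rxns.append(
            Reaction(
                f"PAR_{j}",
                {prev: -1.0, "MP": 1.0},
                0.0,
                1000.0,
                gpr=_gpr_for(fresh_genes(spec.genes_per_reaction), rng),
                subsystem="parallel block",
            )
        )
    rxns.append(Reaction("BIOMASS", {"MP": -1.0}, 0.0, 1000.0, gpr=None, subsystem="biomass"))

    model = MetabolicModel(
        id=f"toy_l{spec.n_linear_reactions}_p{spec.n_parallel_branches}_s{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        objective="BIOMASS",
    )
    model.validate()
    return model


def toy_model_genes(model: MetabolicModel) -> List[str]:
    """All gene ids referenced by the model's GPR rules, in rule order."""
    from .gpr import parse_gpr

    seen: List[str] = []
    for r in model.reactions:
        if r.gpr:
            for g in sorted(parse_gpr(r.gpr).genes()):
                if g not in seen:
                    seen.append(g)
    return seen


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def make_annotation(
    protein_ids: Sequence[str], term_sizes: Mapping[str, int], seed: int = 0
) -> Dict[str, Set[str]]:
    """Disjoint term → protein-set annotation drawn without replacement."""
    total = sum(term_sizes.values())
    if total > len(protein_ids):
        raise ValueError("term sizes exceed the protein pool")
    rng = np.random.default_rng(seed)
    pool = list(rng.permutation(np.asarray(protein_ids, dtype=object)))
    out: Dict[str, Set[str]] = {}
    for term in sorted(term_sizes):
        k = term_sizes[term]
        out[term] = set(pool[:k])
        pool = pool[k:]
    return out


# ---------------------------------------------------------------------------
# synthetic proteomics experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticExperimentSpec:
    """Design of a perturbation experiment.

    ``n_samples`` biological samples (cell-line stand-ins) are measured per
    condition, in duplicate when ``duplicate_pairs`` — mirroring paired
    perturbation experiments.  ``effect_map`` plants per-condition log2
    shifts on the proteins of annotation terms.  Base log2 intensities are
    N(20, 2) (MS-scale); per-measurement noise and replicate noise are in
    log2 units.

    Annotated terms behave as co-regulated modules, as functional modules
    do in real proteomes: each term carries a cell-line-level latent factor
    (sd ``module_sd``, identical in control and treated columns of a line,
    so it cancels exactly in deltas) plus a small per-column jitter (sd
    ``module_jitter_sd``).  The factors give module members high mutual
    correlation across samples, which is what the downstream spanning
    forest exploits.
    """

    n_proteins: int = 200
    n_samples: int = 4
    n_conditions: int = 2
    effect_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    duplicate_pairs: bool = True
    missing_rate: float = 0.0
    seed: int = 0
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.25
    replicate_sd: float = 0.1
    module_sd: float = 1.0
    module_jitter_sd: float = 0.3
    frac_low_peptides: float = 0.0
    protein_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_conditions < 1 or self.n_proteins < 1 or self.n_samples < 1:
            raise ValueError("counts must be >= 1")

    @property
    def conditions(self) -> List[str]:
        treats = [c for c in self.effect_map if c != "control"]
        extra = self.n_conditions - 1 - len(treats)
        treats = sorted(treats) + [f"treated{i + 1}" for i in range(max(0, extra))]
        return ["control"] + treats[: self.n_conditions - 1]


def make_expression(
    spec: SyntheticExperimentSpec, annotation: Mapping[str, Set[str]]
) -> ExpressionMatrix:
    """Generate a raw-intensity matrix with planted condition effects.

    Effects are added on the log2 scale to the proteins of the affected
    terms; intensities are 2**log2-value.  Replicate columns share the
    biological draw and differ by small replicate noise; zeros are injected
    at ``missing_rate``; unique-peptide counts are >=1 with a fraction
    below 2 controlled by ``frac_low_peptides``.  Ground truth (affected
    proteins, forced-low-peptide proteins, zero mask) lands in ``.meta``.
    """
    for cond, effects in spec.effect_map.items():
        unknown = set(effects) - set(annotation)
        if unknown:
            raise KeyError(f"effect_map terms not in annotation: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    if spec.protein_ids is not None:
        if len(spec.protein_ids) > spec.n_proteins:
            raise ValueError("more protein_ids than n_proteins")
        proteins = list(spec.protein_ids) + [
            f"P{i + 1:04d}" for i in range(len(spec.protein_ids), spec.n_proteins)
        ]
    else:
        proteins = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]
    pindex = {p: i for i, p in enumerate(proteins)}

    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=spec.n_proteins)

    effect_per_cond: Dict[str, np.ndarray] = {}
    for cond in spec.conditions:
        eff = np.zeros(spec.n_proteins)
        for term, size in spec.effect_map.get(cond, {}).items():
            for p in annotation[term]:
                if p in pindex:
                    eff[pindex[p]] += size
        effect_per_cond[cond] = eff

    terms = sorted(annotation)
    membership = {
        t: np.array([1.0 if p in annotation[t] else 0.0 for p in proteins]) for t in terms
    }
    # cell-line-level module factors, shared by every column of a line
    line_factor = {t: rng.normal(0.0, spec.module_sd, size=spec.n_samples) for t in terms}

    reps = 2 if spec.duplicate_pairs else 1
    cols, col_meta = [], []
    values = []
    for cond in spec.conditions:
        for s in range(1, spec.n_samples + 1):
            bio = rng.normal(0.0, spec.noise_sd, size=spec.n_proteins)
            module = np.zeros(spec.n_proteins)
            for t in terms:
                module += membership[t] * line_factor[t][s - 1]
            for r in range(1, reps + 1):
                tech = rng.normal(0.0, spec.replicate_sd, size=spec.n_proteins) if reps > 1 else 0.0
                jitter = np.zeros(spec.n_proteins)
                if spec.module_jitter_sd > 0:
                    for t in terms:
                        jitter += membership[t] * rng.normal(0.0, spec.module_jitter_sd)
                y = base + effect_per_cond[cond] + module + jitter + bio + tech
                values.append(np.power(2.0, y))
                name = f"{cond}_line{s}_r{r}"
                cols.append(name)
                col_meta.append({"sample": name, "cell_line": f"line{s}", "condition": cond, "replicate": r})

    arr = np.column_stack(values)
    zero_mask = rng.random(arr.shape) < spec.missing_rate
    arr[zero_mask] = 0.0
    inten = pd.DataFrame(arr, index=proteins, columns=cols)

    n_low = int(round(spec.frac_low_peptides * spec.n_proteins))
    low_idx = rng.choice(spec.n_proteins, size=n_low, replace=False) if n_low else np.array([], dtype=int)
    unique = 2 + rng.poisson(2.0, size=spec.n_proteins)
    unique[low_idx] = 1
    razor = unique + rng.poisson(1.0, size=spec.n_proteins)

    affected = {
        cond: sorted({p for term in effects for p in annotation[term] if p in pindex})
        for cond, effects in spec.effect_map.items()
    }
    return ExpressionMatrix(
        intensities=inten,
        samples=pd.DataFrame(col_meta).set_index("sample"),
        unique_peptides=pd.Series(unique, index=proteins),
        razor_peptides=pd.Series(razor, index=proteins),
        meta={
            "spec": spec,
            "affected": affected,
            "low_peptide_proteins": sorted(proteins[i] for i in low_idx),
            "n_zeros": int(zero_mask.sum()),
        },
    )


def delta_standard_error(
    spec: SyntheticExperimentSpec,
    n_proteins_averaged: int = 1,
    n_lines_averaged: int = 1,
    same_module: bool = True,
) -> float:
    """Analytic standard error of a mean treated − control delta.

    Each per-protein delta averages ``reps`` replicate columns per
    condition; biological noise is shared within a replicate pair, so the
    per-protein contribution is 2(σ_bio² + σ_rep²/reps)/m for m averaged
    proteins.  The cell-line module factor cancels exactly, but the
    per-column module jitter does not and — being shared by every protein
    of the module — adds 2σ_jit²/reps regardless of m when the proteins
    come from one module.  Averaging over L (cell line, drug) pairs divides
    everything by L.
    """
    reps = 2 if spec.duplicate_pairs else 1
    var = 2.0 * (spec.noise_sd ** 2 + spec.replicate_sd ** 2 / reps) / n_proteins_averaged
    if same_module:
        var += 2.0 * spec.module_jitter_sd ** 2 / reps
    return math.sqrt(var / n_lines_averaged)


# ---------------------------------------------------------------------------
# viability tables
# ---------------------------------------------------------------------------

def make_viability(
    m: float,
    Dm: float,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str = "synthetic",
) -> ViabilityTable:
    """Median-effect viability row: 100·(1 − fa(D)), fa = 1/(1 + (Dm/D)^m).

    Dose 0 is fixed at 100 (normalization convention); Gaussian noise of
    ``noise_sd`` percentage points is added to nonzero doses.
    """
    if m <= 0 or Dm <= 0:
        raise ValueError("m and Dm must be positive")
    doses = np.asarray(sorted(doses), dtype=float)
    if (doses < 0).any():
        raise ValueError("doses must be >= 0")
    rng = np.random.default_rng(seed)
    v = np.empty_like(doses)
    for i, d in enumerate(doses):
        if d == 0:
            v[i] = 100.0
        else:
            fa = 1.0 / (1.0 + (Dm / d) ** m)
            v[i] = 100.0 * (1.0 - fa) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return ViabilityTable(data=pd.DataFrame([v], index=[name], columns=doses))
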