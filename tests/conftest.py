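import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fluxnode import (
    ExpressionMatrix,
    MetabolicModel,
    Reaction,
    ToyModelSpec,
    make_toy_model,
)


@pytest.fixture
def chain_model() -> MetabolicModel:
    """Single bottleneck: uptake 10 through a 3-step chain into biomass."""
    return make_toy_model(ToyModelSpec(n_linear_reactions=3, n_parallel_branches=1, uptake_bound=10.0, seed=1))


@pytest.fixture
def parallel_model() -> MetabolicModel:
    """Degenerate optimum: two equivalent routes carry a total of 10."""
    return make_toy_model(ToyModelSpec(n_linear_reactions=1, n_parallel_branches=2, uptake_bound=10.0, seed=1))


@pytest.fixture
def reversible_model() -> MetabolicModel:
    """Tiny model with a reversible internal loop reaction."""
    m = MetabolicModel(
        id="rev_toy",
        metabolites=["A", "B", "C"],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, 5.0),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0.0, 100.0, gpr="g1"),
            Reaction("R_BC", {"B": -1.0, "C": 1.0}, -100.0, 100.0, gpr="g2 and g3"),
            Reaction("BIOMASS", {"C": -1.0}, 0.0, 100.0),
        ],
        objective="BIOMASS",
    )
    m.validate()
    return m


def small_matrix(values, samples=None, peptides=None, log_scale=False) -> ExpressionMatrix:
    """Convenience constructor for hand-written expression fixtures."""
    df = pd.DataFrame(values).T if isinstance(values, dict) else pd.DataFrame(values)
    cols = list(df.columns)
    if samples is None:
        samples = pd.DataFrame(
            {
                "cell_line": ["L1"] * len(cols),
                "condition": ["control"] * len(cols),
                "replicate": list(range(1, len(cols) + 1)),
            },
            index=cols,
        )
    n = len(df.index)
    pep = pd.Series(peptides if peptides is not None else [2] * n, index=df.index)
    return ExpressionMatrix(
        intensities=df.astype(float),
        samples=samples,
        unique_peptides=pep,
        razor_peptides=pep + 1,
        log_scale=log_scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
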