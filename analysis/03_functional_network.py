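#!/usr/bin/env python
"""Correlation spanning forest over the normalized proteome, branch
splitting and enrichment labeling, then functional-node activities — plus
the 100-run recovery study for the planted module."""

from pathlib import Path

import pandas as pd

from fluxnode import build_tree, label_branches, node_activities, split_branches
from fluxnode.experiments import module_recovery_experiment
from fluxnode.network import read_gmt, write_graphml
from fluxnode.prep import DeltaTable, ExpressionMatrix

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    inten = pd.read_csv(ROOT / "prep" / "normalized.tsv", sep="\t", index_col=0)
    design = pd.read_csv(ROOT / "inputs" / "design.tsv", sep="\t", index_col=0)
    x = ExpressionMatrix(
        intensities=inten, samples=design.loc[inten.columns],
        unique_peptides=pd.Series(2, index=inten.index),
        razor_peptides=pd.Series(2, index=inten.index), log_scale=True,
    )
    deltas = pd.read_csv(ROOT / "prep" / "deltas.tsv", sep="\t", index_col=0, header=[0, 1])
    annotation = read_gmt(ROOT / "inputs" / "annotation.gmt")

    net = label_branches(split_branches(build_tree(x), 10), annotation, alpha=0.05)
    acts = node_activities(net, DeltaTable(deltas=deltas))

    out = ROOT / "network"
    out.mkdir(parents=True, exist_ok=True)
    net.to_edgelist().to_csv(out / "edges.tsv", sep="\t", index=False)
    net.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    acts.to_csv(out / "node_activities.tsv", sep="\t")
    write_graphml(net, out / "network.graphml")

    print(f"{len(net.branches)} branches, {len(net.labeled_branches)} labeled")
    print("node activities (mean over cell lines):")
    print(acts.mean(axis=1).round(3).to_string())

    study = module_recovery_experiment(n_runs=100, seed=0)
    pd.Series(study).to_csv(out / "recovery_study.tsv", sep="\t")
    print(
        f"recovery study: planted {study['planted_effect']} recovered within 3 SE in "
        f"{100 * study['recovery_rate']:.0f}% of {study['n_runs']} runs "
        f"(mean activity {study['mean_activity']:.3f})"
    )


if __name__ == "__main__":
    main()
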