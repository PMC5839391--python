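#!/usr/bin/env python
"""Quantifiability filtering, normalization and treated-minus-control
deltas for the simulated proteomics study; reports how many proteins pass
the filters and how many cross the |delta| > 1.5 selection threshold."""

from pathlib import Path

import pandas as pd

from fluxnode import compute_deltas, filter_quantifiable, normalize, read_maxquant, select_changed

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    design = pd.read_csv(ROOT / "inputs" / "design.tsv", sep="\t", index_col=0)
    x = read_maxquant(ROOT / "inputs" / "proteinGroups.txt", design)
    kept = filter_quantifiable(x, min_peptides=2, min_detect_frac=0.75)
    norm = normalize(kept, seed=1)
    deltas = compute_deltas(norm)
    changed = select_changed(deltas, threshold=1.5)

    out = ROOT / "prep"
    out.mkdir(parents=True, exist_ok=True)
    norm.intensities.to_csv(out / "normalized.tsv", sep="\t")
    deltas.deltas.to_csv(out / "deltas.tsv", sep="\t")

    print(f"{len(kept.proteins)}/{len(x.proteins)} proteins pass the quantifiability filters")
    for pair, prots in sorted(changed.items()):
        print(f"  {pair}: {len(prots)} proteins with |delta| > 1.5")
    print(f"wrote {out}/normalized.tsv and {out}/deltas.tsv")


if __name__ == "__main__":
    main()
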