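#!/usr/bin/env python
"""Median-effect fits of the printed viability tables: IC50 (Dm) and slope
m per cell line for both drugs, plus suboptimal (IC70) doses."""

from importlib.resources import files
from pathlib import Path

import pandas as pd

from fluxnode import dose_at_effect, fit_median_effect, fit_table
from fluxnode.dose import read_viability

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "dose_response"
    out.mkdir(parents=True, exist_ok=True)
    for drug, unit in (("mtf", "mM"), ("rp", "nM")):
        vt = read_viability(files("fluxnode") / "data" / f"viability_{drug}.tsv")
        fits = fit_table(vt)
        ic70 = {
            line: dose_at_effect(fit_median_effect(vt.doses, vt.data.loc[line].values), 0.7)
            for line in vt.data.index
        }
        fits["IC70"] = pd.Series(ic70)
        fits.rename_axis("cell_line").to_csv(out / f"fits_{drug}.tsv", sep="\t")
        print(f"--- {drug.upper()} ({unit}) ---")
        print(fits.round(3).to_string())


if __name__ == "__main__":
    main()
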