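"""Median-effect (Chou-Talalay) dose-response analysis.

The median-effect model  fa/(1 − fa) = (D/Dm)^m  relates the affected
fraction fa = 1 − viability/100 to dose D through the median-effect dose Dm
(the IC50) and the sigmoidicity slope m.  Taking logs linearizes it:
log(fa/(1−fa)) = m·log D − m·log Dm, so (m, Dm) come from a least-squares
line.  Points outside the model's dynamic range — viability ≥ 100%
(growth stimulation, fa ≤ 0) or complete kill (fa ≥ 1) — are excluded and
counted, because their log-odds are undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ViabilityTable",
    "DoseResponseFit",
    "fit_median_effect",
    "fit_table",
    "dose_at_effect",
    "read_viability",
]


@dataclass
class ViabilityTable:
    """Viability (% of untreated control) per cell line per dose.

    ``data`` rows are cell lines, columns strictly increasing doses; the
    dose-0 column is 100 by normalization.
    """

    data: pd.DataFrame

    def __post_init__(self):
        doses = np.asarray(self.data.columns, dtype=float)
        if not (np.diff(doses) > 0).all():
            raise ValueError("doses must be strictly increasing")
        self.data.columns = doses

    @property
    def doses(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    def to_tsv(self, path) -> None:
        self.data.rename_axis("cell_line").to_csv(path, sep="\t")


def read_viability(path) -> ViabilityTable:
    """Read a TSV shaped like the printed viability tables: first column
    the cell line, header row the doses."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(float)
    return ViabilityTable(data=df)


@dataclass
class DoseResponseFit:
    m: float           # median-effect slope
    Dm: float          # median-effect dose (IC50), in the input dose units
    r2: float
    n_points_used: int
    n_excluded: int

    def __post_init__(self):
        if self.m <= 0 or self.Dm <= 0:
            raise ValueError("invalid median-effect fit (m and Dm must be positive)")


def fit_median_effect(doses: Sequence[float], viability: Sequence[float]) -> DoseResponseFit:
    """Least-squares median-effect fit on log(fa/(1−fa)) versus log D."""
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    fa = 1.0 - viability / 100.0
    usable = (doses > 0) & (fa > 0) & (fa < 1)
    n_excl = int((~usable).sum())
    if usable.sum() < 2:
        raise ValueError("insufficient dynamic range: fewer than 2 usable dose points")
    x = np.log(doses[usable])
    y = np.log(fa[usable] / (1.0 - fa[usable]))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise ValueError("non-positive median-effect slope; data not dose-responsive")
    Dm = math.exp(-intercept / m)
    yhat = m * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DoseResponseFit(m=float(m), Dm=float(Dm), r2=r2, n_points_used=int(usable.sum()), n_excluded=n_excl)


def fit_table(vt: ViabilityTable) -> pd.DataFrame:
    """Fit every cell line of a viability table; one row per line."""
    rows = {}
    for line, row in vt.data.iterrows():
        fit = fit_median_effect(vt.doses, row.values)
        rows[line] = {
            "m": fit.m,
            "Dm": fit.Dm,
            "r2": fit.r2,
            "n_points_used": fit.n_points_used,
            "n_excluded": fit.n_excluded,
        }
    return pd.DataFrame(rows).T


def dose_at_effect(fit: DoseResponseFit, fa: float) -> float:
    """Dose producing affected fraction fa:  D = Dm · (fa/(1−fa))^(1/m)."""
    if not 0 < fa < 1:
        raise ValueError("fa must be in (0, 1)")
    return fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)
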