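"""Label-free proteomics preprocessing.

Protein-group intensity tables (MaxQuant ``proteinGroups.txt`` style) are
filtered for quantifiability (unique-peptide count and detection fraction),
put through the normalization chain — hyperbolic-arcsine transform,
imputation of missing values (zeros), per-sample median scaling, conversion
to log2 units — and reduced to per-protein treated-minus-control deltas per
cell line and drug.

The arcsinh transform is already logarithmic for MS-scale intensities
(arcsinh x ≈ ln 2x), so the final step expresses the transformed values in
log2 units by dividing by ln 2 rather than taking a second logarithm;
deltas and the conventional |Δ| > 1.5 selection threshold then live on the
log2-intensity scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DeltaTable",
    "read_maxquant",
    "filter_quantifiable",
    "normalize",
    "compute_deltas",
    "select_changed",
]


@dataclass
class ExpressionMatrix:
    """Protein × sample intensities plus per-protein peptide counts.

    ``samples`` carries one row per intensity column with ``cell_line``,
    ``condition`` and ``replicate`` metadata.
    """

    intensities: pd.DataFrame          # proteins x samples
    samples: pd.DataFrame              # index = sample id; cell_line/condition/replicate
    unique_peptides: pd.Series
    razor_peptides: pd.Series
    log_scale: bool = False            # True after normalize()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for columns: {sorted(missing)}")
        if not self.log_scale and (self.intensities.values < 0).any():
            raise ValueError("raw intensities must be non-negative")

    @property
    def proteins(self) -> list:
        return list(self.intensities.index)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            intensities=self.intensities.copy(),
            samples=self.samples.copy(),
            unique_peptides=self.unique_peptides.copy(),
            razor_peptides=self.razor_peptides.copy(),
            log_scale=self.log_scale,
            meta=dict(self.meta),
        )

    # -- MaxQuant-style TSV --------------------------------------------
    def to_maxquant(self, path) -> None:
        out = pd.DataFrame({"Protein IDs": self.intensities.index})
        out["Razor + unique peptides"] = self.razor_peptides.values
        out["Unique peptides"] = self.unique_peptides.values
        for col in self.intensities.columns:
            out[f"Intensity {col}"] = self.intensities[col].values
        out.to_csv(path, sep="\t", index=False)

    def to_design(self, path) -> None:
        self.samples.rename_axis("sample").to_csv(path, sep="\t")


def read_maxquant(groups_path, design: pd.DataFrame) -> ExpressionMatrix:
    """Read a proteinGroups TSV plus a sample design table.

    ``design`` is indexed by sample name (matching the ``Intensity <name>``
    columns) with columns cell_line, condition, replicate.
    """
    df = pd.read_csv(groups_path, sep="\t")
    df = df.set_index("Protein IDs")
    icols = [c for c in df.columns if c.startswith("Intensity ")]
    names = [c[len("Intensity "):] for c in icols]
    unknown = set(names) - set(design.index.astype(str))
    if unknown:
        raise ValueError(f"design has no entry for samples: {sorted(unknown)}")
    inten = df[icols].astype(float)
    inten.columns = names
    unique = (
        df["Unique peptides"] if "Unique peptides" in df else df["Razor + unique peptides"]
    ).astype(int)
    razor = df["Razor + unique peptides"].astype(int)
    return ExpressionMatrix(
        intensities=inten,
        samples=design.loc[names],
        unique_peptides=unique,
        razor_peptides=razor,
    )


def filter_quantifiable(
    x: ExpressionMatrix, min_peptides: int = 2, min_detect_frac: float = 0.75
) -> ExpressionMatrix:
    """Keep proteins with >= min_peptides unique peptides detected (nonzero)
    in at least ceil(min_detect_frac · n_samples) samples.  Idempotent."""
    if not 0 < min_detect_frac <= 1:
        raise ValueError("min_detect_frac must be in (0, 1]")
    need = math.ceil(min_detect_frac * x.n_samples)
    detected = (x.intensities > 0).sum(axis=1)
    keep = (x.unique_peptides.reindex(x.intensities.index) >= min_peptides) & (detected >= need)
    if not keep.any():
        warnings.warn("no protein passes the quantifiability filters")
    out = x.copy()
    out.intensities = out.intensities.loc[keep]
    out.unique_peptides = out.unique_peptides.loc[keep]
    out.razor_peptides = out.razor_peptides.loc[keep]
    return out


def _impute(values: np.ndarray, method: str, seed: int) -> np.ndarray:
    """Impute NaNs column-as-feature.  'rf' mirrors missForest (iterative
    random-forest); 'knn' (k=10) is the fallback for tiny matrices."""
    if method == "auto":
        method = "rf" if values.shape[0] >= 30 and values.shape[1] >= 4 else "knn"
    if method == "rf":
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        imp = IterativeImputer(
            estimator=RandomForestRegressor(n_estimators=10, random_state=seed, n_jobs=1),
            max_iter=10,
            random_state=seed,
            keep_empty_features=True,
        )
    elif method == "knn":
        from sklearn.impute import KNNImputer

        imp = KNNImputer(n_neighbors=min(10, max(1, values.shape[0] - 1)))
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return imp.fit_transform(values)


def normalize(x: ExpressionMatrix, impute_method: str = "auto", seed: int = 0) -> ExpressionMatrix:
    """arcsinh -> impute zeros -> median-scale each sample -> log2 units.

    Median scaling multiplies each sample so its median equals the grand
    median of sample medians; afterwards all sample medians agree to 1e-9.
    Raises on an all-zero protein row (nothing to impute from).
    """
    vals = x.intensities.values.astype(float)
    all_zero = (vals == 0).all(axis=1)
    if all_zero.any():
        bad = list(x.intensities.index[all_zero])
        raise ValueError(f"all-zero protein rows cannot be imputed: {bad[:5]}")

    vals = np.arcsinh(vals)
    if (x.intensities.values == 0).any():
        vals[x.intensities.values == 0] = np.nan
        vals = _impute(vals, impute_method, seed)

    medians = np.median(vals, axis=0)
    if (medians <= 0).any():
        raise ValueError("non-positive sample median; cannot median-scale")
    target = float(np.median(medians))
    vals = vals * (target / medians)[None, :]
    vals = vals / math.log(2)  # arcsinh is natural-log based; express in log2 units

    out = x.copy()
    out.intensities = pd.DataFrame(vals, index=x.intensities.index, columns=x.intensities.columns)
    out.log_scale = True
    return out


@dataclass
class DeltaTable:
    """Per-protein treated − control log2 differences, one column per
    (cell line, drug) pair."""

    deltas: pd.DataFrame  # proteins x MultiIndex (cell_line, drug)

    @property
    def pairs(self) -> list:
        return list(self.deltas.columns)


def compute_deltas(x: ExpressionMatrix, control: str = "control") -> DeltaTable:
    """Average replicates within each (cell line, condition), then subtract
    control from treated per cell line and drug."""
    if not x.log_scale:
        warnings.warn("computing deltas on non-normalized intensities")
    meta = x.samples
    cell_lines = meta["cell_line"].unique()
    drugs = [c for c in meta["condition"].unique() if c != control]
    cols: Dict[Tuple[str, str], pd.Series] = {}
    for cl in cell_lines:
        ctrl_cols = meta.index[(meta["cell_line"] == cl) & (meta["condition"] == control)]
        for drug in drugs:
            trt_cols = meta.index[(meta["cell_line"] == cl) & (meta["condition"] == drug)]
            if len(trt_cols) == 0:
                continue
            if len(ctrl_cols) == 0:
                raise ValueError(f"no control samples for cell line {cl!r} (drug {drug!r})")
            cols[(cl, drug)] = (
                x.intensities[trt_cols].mean(axis=1) - x.intensities[ctrl_cols].mean(axis=1)
            )
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cell_line", "drug"])
    return DeltaTable(deltas=out)


def select_changed(d: DeltaTable, threshold: float = 1.5) -> Dict[Tuple[str, str], Set[str]]:
    """Proteins with |delta| strictly greater than the threshold, per pair."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return {
        pair: set(d.deltas.index[d.deltas[pair].abs() > threshold]) for pair in d.deltas.columns
    }
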