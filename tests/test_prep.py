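"""Quantifiability filters, normalization chain and delta computation."""

import numpy as np
import pandas as pd
import pytest

from fluxnode import (
    SyntheticExperimentSpec,
    compute_deltas,
    delta_standard_error,
    filter_quantifiable,
    make_annotation,
    make_expression,
    normalize,
    read_maxquant,
    select_changed,
)
from fluxnode.prep import DeltaTable

from conftest import small_matrix


def paired_design(n_lines=1, reps=2):
    rows = []
    for cond in ("control", "treated"):
        for s in range(1, n_lines + 1):
            for r in range(1, reps + 1):
                rows.append(
                    {"sample": f"{cond}_L{s}_r{r}", "cell_line": f"L{s}", "condition": cond, "replicate": r}
                )
    return pd.DataFrame(rows).set_index("sample")


class TestFilter:
    def test_peptide_and_detection_rules(self):
        x = small_matrix(
            pd.DataFrame(
                {
                    "s1": [10.0, 10.0, 10.0],
                    "s2": [10.0, 10.0, 0.0],
                    "s3": [10.0, 10.0, 0.0],
                    "s4": [10.0, 10.0, 10.0],
                },
                index=["P1", "P2", "P3"],
            ),
            peptides=[2, 1, 3],
        )
        kept = filter_quantifiable(x, min_peptides=2, min_detect_frac=0.75)
        assert kept.proteins == ["P1"]  # P2: 1 peptide; P3: 50% detected

    def test_identity_when_nothing_below_threshold(self):
        x = small_matrix(pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=["P1", "P2"]))
        kept = filter_quantifiable(x, min_peptides=2, min_detect_frac=1.0)
        assert kept.proteins == ["P1", "P2"]

    def test_idempotent(self):
        x = small_matrix(
            pd.DataFrame({"s1": [1.0, 0.0], "s2": [1.0, 2.0]}, index=["P1", "P2"]), peptides=[2, 2]
        )
        once = filter_quantifiable(x, 2, 0.75)
        twice = filter_quantifiable(once, 2, 0.75)
        assert once.proteins == twice.proteins

    def test_ground_truth_count_recovered(self):
        """Proteins the generator forces below the peptide threshold are
        exactly the ones removed."""
        spec = SyntheticExperimentSpec(n_proteins=200, n_samples=2, seed=7, frac_low_peptides=0.2)
        ann = make_annotation([f"P{i+1:04d}" for i in range(200)], {"t": 10}, seed=7)
        x = make_expression(spec, ann)
        kept = filter_quantifiable(x, min_peptides=2, min_detect_frac=0.75)
        low = set(x.meta["low_peptide_proteins"])
        assert len(low) == 40
        assert set(kept.proteins) == set(x.proteins) - low

    def test_empty_result_warns(self):
        x = small_matrix(pd.DataFrame({"s1": [1.0]}, index=["P1"]), peptides=[1])
        with pytest.warns(UserWarning, match="no protein passes"):
            filter_quantifiable(x, 2, 0.75)


class TestNormalize:
    def test_sample_medians_equalized(self):
        rng = np.random.default_rng(1)
        x = small_matrix(pd.DataFrame(rng.lognormal(12, 1, (51, 4)), columns=list("abcd")))
        out = normalize(x)
        med = out.intensities.median(axis=0)
        assert np.ptp(med.values) < 1e-9

    def test_order_preserving_within_sample(self):
        rng = np.random.default_rng(2)
        x = small_matrix(pd.DataFrame(rng.lognormal(12, 1, (31, 3)), columns=list("abc")))
        out = normalize(x)
        for col in x.intensities:
            assert (
                out.intensities[col].rank().values == x.intensities[col].rank().values
            ).all()

    def test_all_zero_row_rejected(self):
        x = small_matrix(pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 2.0]}, index=["P1", "P2"]))
        with pytest.raises(ValueError, match="all-zero"):
            normalize(x)

    def test_zeros_are_imputed_positive(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(12, 1, (40, 6))
        vals[rng.random(vals.shape) < 0.1] = 0.0
        vals[0, :] = rng.lognormal(12, 1, 6)  # keep every row partially observed
        x = small_matrix(pd.DataFrame(vals, columns=list("abcdef")))
        out = normalize(x, impute_method="knn")
        assert (out.intensities.values > 0).all()

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.lognormal(12, 1, (20, 4)), columns=list("abcd"),
                          index=[f"P{i}" for i in range(20)])
        x = small_matrix(df)
        perm = list(rng.permutation(df.index))
        xp = small_matrix(df.loc[perm])
        a = normalize(x).intensities.loc[perm]
        b = normalize(xp).intensities
        assert np.allclose(a.values, b.values)


class TestDeltas:
    def test_replicate_means_subtracted(self):
        design = paired_design()
        df = pd.DataFrame(
            {"control_L1_r1": [4.0], "control_L1_r2": [4.0], "treated_L1_r1": [5.0], "treated_L1_r2": [7.0]},
            index=["P1"],
        )
        x = small_matrix(df, samples=design, log_scale=True)
        d = compute_deltas(x)
        assert d.deltas.loc["P1", ("L1", "treated")] == pytest.approx(2.0)

    def test_identical_conditions_give_zero(self):
        design = paired_design()
        df = pd.DataFrame(
            {c: [3.0, 1.0] for c in design.index}, index=["P1", "P2"]
        )
        x = small_matrix(df, samples=design, log_scale=True)
        assert (compute_deltas(x).deltas.values == 0).all()

    def test_label_swap_negates(self):
        design = paired_design()
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(20, 1, (10, 4)), columns=design.index)
        x = small_matrix(df, samples=design, log_scale=True)
        swapped = design.copy()
        swapped["condition"] = swapped["condition"].map({"control": "treated", "treated": "control"})
        y = small_matrix(df, samples=swapped, log_scale=True)
        assert np.allclose(compute_deltas(x).deltas.values, -compute_deltas(y).deltas.values)

    def test_missing_control_names_the_pair(self):
        design = paired_design()
        design = design[design["condition"] == "treated"]
        df = pd.DataFrame({c: [1.0] for c in design.index}, index=["P1"])
        x = small_matrix(df, samples=design, log_scale=True)
        with pytest.raises(ValueError, match="L1"):
            compute_deltas(x)

    def test_planted_effect_recovered_through_full_chain(self):
        """A -1.0 log2 effect on an annotated module survives filtering,
        normalization and delta computation to within 3 SE."""
        proteins = [f"P{i+1:04d}" for i in range(200)]
        ann = make_annotation(proteins, {"mito": 20, "other": 20}, seed=11)
        spec = SyntheticExperimentSpec(
            n_proteins=200, n_samples=4, effect_map={"treated1": {"mito": -1.0}}, seed=11
        )
        x = make_expression(spec, ann)
        d = compute_deltas(normalize(filter_quantifiable(x)))
        mito = sorted(ann["mito"])
        mean_delta = d.deltas.loc[mito].values.mean()
        se = delta_standard_error(spec, len(mito), d.deltas.shape[1])
        assert mean_delta == pytest.approx(-1.0, abs=3 * se)


class TestSelectChanged:
    def test_strict_threshold(self):
        d = DeltaTable(
            deltas=pd.DataFrame(
                {("L1", "drug"): {"a": 1.6, "b": 1.4, "c": -1.6, "d": 1.5}},
            )
        )
        d.deltas.columns = pd.MultiIndex.from_tuples(d.deltas.columns, names=["cell_line", "drug"])
        out = select_changed(d, 1.5)
        assert out[("L1", "drug")] == {"a", "c"}  # 1.5 itself excluded (strict)

    def test_zero_threshold_selects_all_nonzero(self):
        d = DeltaTable(deltas=pd.DataFrame({("L1", "x"): {"a": 0.1, "b": -0.2}}))
        d.deltas.columns = pd.MultiIndex.from_tuples(d.deltas.columns, names=["cell_line", "drug"])
        assert select_changed(d, 0.0)[("L1", "x")] == {"a", "b"}


class TestIO:
    def test_maxquant_round_trip(self, tmp_path):
        spec = SyntheticExperimentSpec(n_proteins=30, n_samples=2, seed=3, missing_rate=0.1)
        ann = make_annotation([f"P{i+1:04d}" for i in range(30)], {"t": 5}, seed=3)
        x = make_expression(spec, ann)
        x.to_maxquant(tmp_path / "pg.txt")
        x.to_design(tmp_path / "design.tsv")
        design = pd.read_csv(tmp_path / "design.tsv", sep="\t", index_col=0)
        back = read_maxquant(tmp_path / "pg.txt", design)
        assert np.allclose(back.intensities.values, x.intensities.values)
        assert (back.unique_peptides.values == x.unique_peptides.values).all()
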