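"""Spanning-forest construction, branch splitting, enrichment labels,
node activities and response regression."""

import numpy as np
import pandas as pd
import pytest

from fluxnode import (
    FunctionalNetwork,
    build_tree,
    fit_response_model,
    label_branches,
    node_activities,
    split_branches,
)
from fluxnode.prep import DeltaTable

from conftest import small_matrix
from oracles import hypergeom_tail, max_spanning_tree_weight


def matrix_from_rows(rows: dict, log_scale=True):
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return small_matrix(df, log_scale=log_scale)


class TestBuildTree:
    def test_three_node_tree_keeps_heaviest_pair(self):
        # construct samples so |rho|(1,2) > |rho|(1,3) >> |rho|(2,3)
        base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        rows = {
            "p1": base,
            "p2": base + [0.01, -0.02, 0.015, 0.0, -0.01, 0.02],
            "p3": base[::-1] * 0.9 + [0.3, -0.4, 0.5, -0.2, 0.25, -0.3],
        }
        net = build_tree(matrix_from_rows(rows))
        got = {(u, v) for u, v, _ in net.edges}
        assert got == {("p1", "p2"), ("p1", "p3")}

    def test_duplicated_rows_are_adjacent(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(5, 8))
        rows = {f"p{i}": data[i] for i in range(5)}
        rows["p_dup"] = rows["p0"].copy()  # |rho| = 1 with p0
        net = build_tree(matrix_from_rows(rows))
        assert any({u, v} == {"p0", "p_dup"} for u, v, _ in net.edges)

    def test_edge_count_is_n_minus_1(self):
        rng = np.random.default_rng(1)
        rows = {f"p{i}": rng.normal(size=10) for i in range(7)}
        net = build_tree(matrix_from_rows(rows))
        assert len(net.edges) == 6
        assert len(net.branches) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_total_weight_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        rows = {f"p{i}": rng.normal(size=9) for i in range(n)}
        x = matrix_from_rows(rows)
        corr = np.abs(np.corrcoef(x.intensities.values))
        nodes = sorted(rows)
        idx = {p: i for i, p in enumerate(x.intensities.index)}
        weights = {
            (nodes[i], nodes[j]): corr[idx[nodes[i]], idx[nodes[j]]]
            for i in range(n)
            for j in range(i + 1, n)
        }
        net = build_tree(x)
        got = sum(w for _, _, w in net.edges)
        assert got == pytest.approx(max_spanning_tree_weight(nodes, weights), abs=1e-12)

    def test_constant_protein_excluded_with_warning(self):
        rows = {"p1": np.arange(6.0), "p2": np.arange(6.0) * 2, "p3": np.ones(6)}
        with pytest.warns(UserWarning, match="constant"):
            net = build_tree(matrix_from_rows(rows))
        assert "p3" not in net.nodes

    def test_too_few_samples_rejected(self):
        rows = {"p1": [1.0, 2.0], "p2": [2.0, 1.0]}
        with pytest.raises(ValueError, match="3 samples"):
            build_tree(matrix_from_rows(rows))


def chain_net():
    return FunctionalNetwork(
        nodes=["a", "b", "c"],
        edges=[("a", "b", 0.9), ("b", "c", 0.2)],
        branches=[frozenset({"a", "b", "c"})],
    )


class TestSplitBranches:
    def test_identity_at_one_branch(self):
        net = split_branches(chain_net(), 1)
        assert net.branches == [frozenset({"a", "b", "c"})]

    def test_singletons_at_node_count(self):
        net = split_branches(chain_net(), 3)
        assert sorted(len(b) for b in net.branches) == [1, 1, 1]

    def test_lightest_edge_cut_first(self):
        net = split_branches(chain_net(), 2)
        assert set(net.branches) == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_monotone_refinement(self):
        """Increasing the branch count only ever splits, never merges."""
        rng = np.random.default_rng(2)
        rows = {f"p{i}": rng.normal(size=10) for i in range(12)}
        base = build_tree(matrix_from_rows(rows))
        prev = split_branches(base, 2).branches
        for k in range(3, 9):
            cur = split_branches(base, k).branches
            for c in cur:
                assert any(c <= p for p in prev)
            prev = cur

    def test_bad_branch_count_rejected(self):
        with pytest.raises(ValueError):
            split_branches(chain_net(), 0)


class TestLabelBranches:
    def test_pvalue_matches_exact_tail_sum(self):
        nodes = [f"p{i}" for i in range(100)]
        branch = frozenset(nodes[:5])
        rest = frozenset(nodes[5:])
        net = FunctionalNetwork(nodes=nodes, edges=[], branches=[branch, rest])
        term_set = set(nodes[:4]) | {nodes[50]} | {nodes[60]} | {nodes[70]} | \
            {nodes[80]} | {nodes[90]} | {nodes[95]}  # 4 in branch, 10 total
        net = label_branches(net, {"T": term_set}, alpha=0.05)
        row = net.enrichment.query("branch == 0 and term == 'T'").iloc[0]
        assert row["p"] == pytest.approx(hypergeom_tail(4, 100, 10, 5), rel=1e-12)
        assert net.labels[0] == "T"

    def test_absent_term_never_selected(self):
        nodes = list("abcdef")
        net = FunctionalNetwork(nodes=nodes, edges=[], branches=[frozenset("abc"), frozenset("def")])
        net = label_branches(net, {"T": {"d", "e", "f"}}, alpha=0.5)
        assert net.labels[0] is None  # T has no member in branch 0
        assert net.labels[1] == "T"

    def test_alpha_zero_labels_nothing(self):
        nodes = list("abcd")
        net = FunctionalNetwork(nodes=nodes, edges=[], branches=[frozenset("ab"), frozenset("cd")])
        net = label_branches(net, {"T": {"a", "b"}}, alpha=0.0)
        assert all(t is None for t in net.labels.values())

    def test_empty_annotation_gives_all_none(self):
        nodes = list("abcd")
        net = FunctionalNetwork(nodes=nodes, edges=[], branches=[frozenset(nodes)])
        net = label_branches(net, {}, alpha=0.05)
        assert net.labels == {0: None}


def labeled_toy_net():
    nodes = ["a", "b", "c", "d", "e", "f"]
    net = FunctionalNetwork(nodes=nodes, edges=[], branches=[frozenset("abc"), frozenset("def")])
    # generous alpha so both toy branches (p = 0.5 and 0.95) get the label
    return label_branches(net, {"T": {"a", "b", "f"}}, alpha=0.96)


class TestNodeActivities:
    def _deltas(self, values):
        df = pd.DataFrame({("L1", "drug"): values})
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["cell_line", "drug"])
        return DeltaTable(deltas=df)

    def test_mean_over_label_annotated_members_only(self):
        net = labeled_toy_net()
        d = self._deltas({"a": 1.0, "b": 3.0, "c": 100.0, "d": 0.0, "e": 0.0, "f": 5.0})
        acts = node_activities(net, d)
        assert acts.loc["n0:T"].iloc[0] == pytest.approx(2.0)  # c not annotated with T
        assert acts.loc["n1:T"].iloc[0] == pytest.approx(5.0)

    def test_zero_deltas_zero_activities(self):
        net = labeled_toy_net()
        d = self._deltas({p: 0.0 for p in "abcdef"})
        assert (node_activities(net, d).values == 0).all()

    def test_linearity_in_deltas(self):
        net = labeled_toy_net()
        d1 = self._deltas({"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0, "e": 1.0, "f": -1.0})
        d3 = self._deltas({p: 3 * v for p, v in
                           {"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0, "e": 1.0, "f": -1.0}.items()})
        assert np.allclose(3 * node_activities(net, d1).values, node_activities(net, d3).values)

    def test_unlabeled_network_rejected(self):
        net = FunctionalNetwork(nodes=["a"], edges=[], branches=[frozenset("a")])
        with pytest.raises(ValueError, match="not labeled"):
            node_activities(net, self._deltas({"a": 1.0}))


class TestResponseRegression:
    def test_exact_linear_relation_found(self, rng):
        f = pd.DataFrame(rng.normal(size=(6, 3)), columns=["f1", "f2", "f3"])
        y = pd.Series(2 * f["f1"] - f["f2"])
        res = fit_response_model(f, y, max_terms=2)
        assert res.predictors == ("f1", "f2")
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-10)
        assert res.coefficients["f1"] == pytest.approx(2.0)

    def test_orthogonal_response_near_zero(self):
        rng = np.random.default_rng(42)
        f = pd.DataFrame(rng.normal(size=(50, 5)), columns=[f"f{i}" for i in range(5)])
        y = pd.Series(rng.normal(size=50))
        res = fit_response_model(f, y, max_terms=2)
        assert abs(res.adjusted_r2) < 0.15

    def test_identity_feature(self, rng):
        f = pd.DataFrame({"f1": rng.normal(size=8)})
        res = fit_response_model(f, pd.Series(f["f1"]), max_terms=1)
        assert res.coefficients["f1"] == pytest.approx(1.0, abs=1e-10)
        assert res.coefficients["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_subset_skipped_with_warning(self, rng):
        v = rng.normal(size=8)
        f = pd.DataFrame({"f1": v, "f2": 2 * v, "f3": rng.normal(size=8)})
        y = pd.Series(rng.normal(size=8))
        with pytest.warns(UserWarning, match="collinear"):
            res = fit_response_model(f, y, max_terms=2)
        assert set(res.predictors) != {"f1", "f2"}

    def test_too_few_observations_rejected(self, rng):
        f = pd.DataFrame({"f1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_response_model(f, pd.Series([1.0, 2.0]), max_terms=1)
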