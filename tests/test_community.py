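import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccnet import (
    assign_membership,
    canonical_form,
    cap_grade,
    compare_members,
    consensus_partition,
    hypergeometric_membership,
    label_propagation,
    modularity,
    name_modules_by_cap,
)
from ccnet.community import relabel_membership, relabel_partition
from conftest import random_graph
from oracles import hypergeom_upper_tail, modularity_double_sum


def two_triangles():
    graph = nx.Graph()
    graph.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
    return graph


class TestLabelPropagation:
    def test_disjoint_triangles_always_split(self):
        graph = two_triangles()
        for seed in range(10):
            part = label_propagation(graph, seed=seed)
            assert canonical_form(part) == (("a", "b", "c"), ("x", "y", "z"))

    def test_complete_graph_single_module(self):
        part = label_propagation(nx.complete_graph(5), seed=0)
        assert len(set(part.values())) == 1

    def test_bridged_cliques_usually_split(self):
        graph = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        graph.add_edge(0, 5)
        target = canonical_form({n: (0 if n < 5 else 1) for n in graph})
        hits = sum(
            canonical_form(label_propagation(graph, seed=s)) == target
            for s in range(100)
        )
        assert hits > 50

    def test_isolates_excluded_and_edgeless_rejected(self):
        graph = two_triangles()
        graph.add_node("iso")
        part = label_propagation(graph, seed=1)
        assert "iso" not in part
        with pytest.raises(ValueError, match="edge"):
            label_propagation(nx.empty_graph(3))


class TestConsensusPartition:
    def test_stable_graph_returns_its_partition(self):
        part = consensus_partition(two_triangles(), n_runs=50, seed=0)
        assert canonical_form(part) == (("a", "b", "c"), ("x", "y", "z"))

    def test_deterministic_given_seed(self):
        graph = random_graph(12, 0.4, seed=3)
        assert consensus_partition(graph, 20, seed=5) == consensus_partition(graph, 20, seed=5)

    def test_recovers_planted_blocks(self, small_cohort, fast_edge_config):
        from ccnet import binarize, build_graph, consumption_score, validate_edges

        intake, _, truth = small_cohort
        graph = build_graph(
            validate_edges(intake, fast_edge_config),
            consumption_score(binarize(intake)),
        )
        part = consensus_partition(graph, n_runs=25, seed=1)
        modules = {}
        for node, mod in part.items():
            modules.setdefault(mod, set()).add(node)
        planted = truth["partition"]
        # every recovered module is (a subset of) one planted block
        for members in modules.values():
            assert len({planted[n] for n in members if n in planted}) == 1

    @given(st.permutations(list(range(4))))
    def test_canonical_form_is_relabel_invariant(self, relabel):
        base = {"a": 0, "b": 0, "c": 1, "d": 2, "e": 3}
        renamed = {node: relabel[mod] for node, mod in base.items()}
        assert canonical_form(base) == canonical_form(renamed)


class TestModularity:
    def test_single_module_is_zero(self):
        graph = random_graph(8, 0.5, seed=0)
        part = {n: 0 for n in graph if graph.degree(n) > 0}
        assert modularity(graph, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_is_half(self):
        part = {"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1}
        assert modularity(two_triangles(), part) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_graph(8, 0.45, seed=seed)
        if graph.number_of_edges() == 0:
            pytest.skip("edgeless draw")
        part = {n: int(rng.integers(3)) for n in graph}
        q = modularity(graph, part)
        assert q == pytest.approx(
            modularity_double_sum(list(graph.nodes), list(graph.edges), part), abs=1e-12
        )
        assert -1.0 <= q <= 1.0

    def test_matches_networkx(self):
        graph = random_graph(10, 0.4, seed=2)
        part = {n: (0 if int(n[1:]) < 5 else 1) for n in graph}
        communities = [{n for n in graph if part[n] == c} for c in (0, 1)]
        assert modularity(graph, part) == pytest.approx(
            nx.community.modularity(graph, communities), abs=1e-12
        )


class TestHypergeometricMembership:
    def _row(self, consumed, groups):
        return pd.Series([1 if g in consumed else 0 for g in groups], index=groups)

    def test_all_inside_is_enriched(self):
        groups = [f"g{i}" for i in range(10)]
        partition = {g: ("m1" if i < 5 else "m2") for i, g in enumerate(groups)}
        row = self._row({"g0", "g1", "g2", "g3"}, groups)
        label, pvals = hypergeometric_membership(row, partition, p_threshold=0.1)
        assert pvals["m1"] == pytest.approx(5 / 210)  # C(5,4)/C(10,4)
        assert label == "m1"

    def test_two_inside_is_not_enriched(self):
        groups = [f"g{i}" for i in range(10)]
        partition = {g: ("m1" if i < 5 else "m2") for i, g in enumerate(groups)}
        row = self._row({"g0", "g1", "g5", "g6"}, groups)
        label, pvals = hypergeometric_membership(row, partition)
        assert pvals["m1"] == pytest.approx(155 / 210)
        assert label == "other"

    def test_consuming_nothing_is_other(self):
        groups = [f"g{i}" for i in range(6)]
        partition = {g: ("m1" if i < 3 else "m2") for i, g in enumerate(groups)}
        label, pvals = hypergeometric_membership(self._row(set(), groups), partition)
        assert label == "other"
        assert pvals["m1"] == pytest.approx(1.0) and pvals["m2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("big_n, big_k, n", [(10, 4, 6), (25, 10, 12), (38, 20, 28)])
    def test_pvalues_match_enumeration_and_decrease_in_k(self, big_n, big_k, n):
        from scipy.stats import hypergeom

        previous = 1.1
        for k in range(0, min(big_k, n) + 1):
            p = float(hypergeom.sf(k - 1, big_n, big_k, n))
            assert p == pytest.approx(hypergeom_upper_tail(k, big_n, big_k, n), abs=1e-12)
            assert p <= previous + 1e-12
            previous = p

    def test_vectorized_agrees_with_rowwise(self):
        rng = np.random.default_rng(0)
        groups = [f"g{i}" for i in range(12)]
        partition = {g: ("A" if i < 7 else "B") for i, g in enumerate(groups)}
        binarized = pd.DataFrame(
            rng.integers(0, 2, size=(40, 12)), columns=groups,
            index=[f"p{i}" for i in range(40)],
        )
        table = assign_membership(binarized, partition, p_threshold=0.1)
        for pid in binarized.index:
            label, pvals = hypergeometric_membership(binarized.loc[pid], partition, 0.1)
            assert table.loc[pid, "label"] == label
            assert table.loc[pid, "p_A"] == pytest.approx(pvals["A"], abs=1e-12)
            assert table.loc[pid, "p_B"] == pytest.approx(pvals["B"], abs=1e-12)

    def test_trichotomy_holds_for_everyone(self, small_cohort):
        from ccnet import binarize

        intake, _, truth = small_cohort
        table = assign_membership(binarize(intake), truth["partition"], 0.1)
        below = (table[["p_healthy", "p_unhealthy"]] < 0.1).sum(axis=1)
        assert (table.loc[below != 1, "label"] == "other").all()
        assert (table.loc[below == 1, "label"] != "other").all()


class TestCapGrade:
    @pytest.mark.parametrize(
        "cap, grade",
        [(237.9, "S0"), (238.0, "S1"), (250.0, "S1"), (259.9, "S1"),
         (260.0, "S2"), (292.9, "S2"), (293.0, "S3"), (300.0, "S3")],
    )
    def test_boundaries(self, cap, grade):
        assert cap_grade(cap) == grade

    def test_monotone_step_function(self):
        caps = np.linspace(100, 400, 301)
        grades = cap_grade(caps)
        order = {"S0": 0, "S1": 1, "S2": 2, "S3": 3}
        ranks = [order[g] for g in grades]
        assert ranks == sorted(ranks)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cap_grade(0.0)


class TestCompareMembers:
    def _membership(self, labels):
        return pd.DataFrame(
            {"label": labels}, index=[f"p{i}" for i in range(len(labels))]
        )

    def _covariates(self, n, caps=None, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        return pd.DataFrame(
            {
                "age": rng.uniform(20, 60, n),
                "sex": rng.choice(["male", "female"], n),
                "bmi": rng.uniform(20, 35, n),
                "energy": rng.uniform(1800, 3200, n),
                "cap": caps if caps is not None else rng.uniform(150, 350, n),
            },
            index=[f"p{i}" for i in range(n)],
        )

    def test_identical_groups_give_t_zero_p_one(self):
        membership = self._membership(["unhealthy"] * 3 + ["healthy"] * 3)
        cov = self._covariates(6)
        cov.iloc[3:, [0, 2, 3, 4]] = cov.iloc[:3, [0, 2, 3, 4]].to_numpy()
        result = compare_members(membership, cov)
        assert (result.continuous["t"].abs() < 1e-12).all()
        assert np.allclose(result.continuous["p"], 1.0)

    def test_pooled_t_matches_closed_form(self):
        membership = self._membership(["unhealthy"] * 3 + ["healthy"] * 3)
        cov = self._covariates(6)
        cov["age"] = [1, 2, 3, 4, 5, 6]
        result = compare_members(membership, cov)
        # means 2 and 5, pooled variance 1, se = sqrt(2/3)
        expected_t = (2 - 5) / math.sqrt(2 / 3)
        assert result.continuous.loc["age", "t"] == pytest.approx(expected_t)
        from scipy.stats import t as t_dist

        expected_p = 2 * t_dist.sf(abs(expected_t), df=4)
        assert result.continuous.loc["age", "p"] == pytest.approx(expected_p)

    def test_small_group_rejected(self):
        membership = self._membership(["unhealthy", "healthy", "healthy"])
        with pytest.raises(ValueError, match=">= 2"):
            compare_members(membership, self._covariates(3))

    def test_synthetic_unhealthy_members_have_higher_cap(self, small_cohort):
        from ccnet import binarize

        intake, cov, truth = small_cohort
        membership = assign_membership(binarize(intake), truth["partition"], 0.1)
        result = compare_members(membership, cov)
        assert (
            result.continuous.loc["cap", "mean_unhealthy"]
            > result.continuous.loc["cap", "mean_healthy"]
        )
        assert result.continuous.loc["cap", "p"] < 0.001
        grades = result.categorical.query("variable == 'steatosis_grade'")
        assert grades[["n_unhealthy", "n_healthy"]].to_numpy().sum() == result.n_a + result.n_b


class TestModuleNaming:
    def test_naming_follows_cap_and_relabeling_is_consistent(self, small_cohort):
        from ccnet import binarize

        intake, cov, truth = small_cohort
        partition = {n: {"healthy": 0, "unhealthy": 1}[b] for n, b in truth["partition"].items()}
        membership = assign_membership(binarize(intake), partition, 0.1)
        naming = name_modules_by_cap(membership, cov, partition)
        assert sorted(naming.values()) == ["healthy", "unhealthy"]
        named = relabel_membership(membership, naming)
        named_partition = relabel_partition(partition, naming)
        # the module named unhealthy must be the planted unhealthy block
        unhealthy_nodes = {n for n, m in named_partition.items() if m == "unhealthy"}
        assert unhealthy_nodes == {n for n, b in truth["partition"].items() if b == "unhealthy"}
        assert set(named["label"].unique()) <= {"healthy", "unhealthy", "other"}
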