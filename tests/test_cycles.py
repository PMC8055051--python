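"""The four cycle-removal methods and their hierarchy machinery."""

import networkx as nx
import numpy as np
import pytest
from _oracles import agony_optimum, mfas_optimum

from kegg2net.cycles import (
    METHODS,
    NodeScores,
    agony_of_ranking,
    convert,
    min_agony_ranking,
    pagerank_scores,
    remove_by_hierarchy,
    remove_cycles_dfs,
    remove_cycles_ensemble,
    remove_cycles_mfas,
    remove_cycles_pagerank,
    trueskill_scores,
)
from kegg2net.fixtures import random_gene_network
from kegg2net.network import ContractError, GeneNetwork

TRIANGLE = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
CHAIN = GeneNetwork.from_edges([("a", "b"), ("b", "c")])


def is_dag(net: GeneNetwork) -> bool:
    return nx.is_directed_acyclic_graph(net.to_networkx())


class TestDFS:
    def test_triangle_removes_closing_edge(self):
        res = remove_cycles_dfs(TRIANGLE)
        assert res.removed_edges == [("c", "a")]
        assert is_dag(res.dag)

    def test_acyclic_untouched(self):
        res = remove_cycles_dfs(CHAIN)
        assert res.removed_edges == [] and res.dag == CHAIN

    def test_two_disjoint_two_cycles(self):
        g = GeneNetwork.from_edges([("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")])
        res = remove_cycles_dfs(g)
        assert res.n_removed == 2 == mfas_optimum(g.genes, g.edges)
        assert is_dag(res.dag)


class TestMFAS:
    def test_triangle_attains_optimum(self):
        res = remove_cycles_mfas(TRIANGLE)
        assert res.n_removed == 1 and is_dag(res.dag)

    def test_acyclic_untouched(self):
        assert remove_cycles_mfas(CHAIN).n_removed == 0

    @pytest.mark.parametrize("seed", range(30))
    def test_never_beats_brute_force_optimum(self, seed):
        rng = np.random.default_rng(seed)
        g = random_gene_network(int(rng.integers(3, 7)), int(rng.integers(2, 14)), seed=seed)
        res = remove_cycles_mfas(g)
        assert res.n_removed >= mfas_optimum(g.genes, g.edges)
        assert is_dag(res.dag)


class TestPageRank:
    def test_symmetric_two_cycle_splits_evenly(self):
        s = pagerank_scores(GeneNetwork.from_edges([("a", "b"), ("b", "a")]))
        assert s.score["a"] == pytest.approx(0.5, abs=1e-8)
        assert s.score["b"] == pytest.approx(0.5, abs=1e-8)

    def test_star_center_dominates(self):
        s = pagerank_scores(GeneNetwork.from_edges([("b", "a"), ("c", "a"), ("d", "a")]))
        assert s.score["a"] > s.score["b"]
        assert s.score["b"] == pytest.approx(s.score["c"]) == pytest.approx(s.score["d"])

    @pytest.mark.parametrize("seed", range(10))
    def test_scores_conserve_mass(self, seed):
        g = random_gene_network(12, 20, seed=seed)
        assert sum(pagerank_scores(g, tol=1e-10).score.values()) == pytest.approx(1.0, abs=1e-9)

    def test_pr_two_cycle_removes_one_edge(self):
        res = remove_cycles_pagerank(GeneNetwork.from_edges([("a", "b"), ("b", "a")]))
        assert res.n_removed == 1 and is_dag(res.dag)

    def test_pr_acyclic_untouched(self):
        assert remove_cycles_pagerank(CHAIN).n_removed == 0


class TestRemoveByHierarchy:
    def test_ascending_chain_keeps_everything(self):
        scores = NodeScores("pagerank", {"a": 1.0, "b": 2.0, "c": 3.0})
        assert remove_by_hierarchy(CHAIN, scores).n_removed == 0

    def test_triangle_removes_only_violating_edge(self):
        scores = NodeScores("pagerank", {"a": 1.0, "b": 2.0, "c": 3.0})
        res = remove_by_hierarchy(TRIANGLE, scores)
        assert res.removed_edges == [("c", "a")] and is_dag(res.dag)

    def test_all_equal_scores_resolved_lexicographically(self):
        g = GeneNetwork.from_edges([("a", "b")])
        assert remove_by_hierarchy(g, NodeScores("pagerank", {"a": 0.0, "b": 0.0})).n_removed == 0

    def test_missing_score_is_contract_error(self):
        with pytest.raises(ContractError):
            remove_by_hierarchy(CHAIN, NodeScores("pagerank", {"a": 1.0}))


class TestTrueSkill:
    def test_single_edge_winner_outranks_loser(self):
        s = trueskill_scores(GeneNetwork.from_edges([("a", "b")]), epochs=1, seed=0)
        assert s.score["b"] > s.score["a"]

    def test_chain_orders_monotonically(self):
        s = trueskill_scores(CHAIN, epochs=10, seed=0)
        assert s.score["a"] < s.score["b"] < s.score["c"]

    def test_seeded_determinism_is_bit_identical(self):
        g = random_gene_network(10, 25, seed=3)
        assert trueskill_scores(g, seed=11).score == trueskill_scores(g, seed=11).score


class TestAgony:
    def test_formula_values(self):
        g = GeneNetwork.from_edges([("a", "b")])
        assert agony_of_ranking(g, NodeScores("agony", {"a": 0, "b": 1})) == 0
        assert agony_of_ranking(g, NodeScores("agony", {"a": 0, "b": 0})) == 1
        assert agony_of_ranking(TRIANGLE, NodeScores("agony", {"a": 0, "b": 1, "c": 2})) == 3

    def test_non_integer_ranks_rejected(self):
        g = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(ContractError):
            agony_of_ranking(g, NodeScores("agony", {"a": 0.5, "b": 1.0}))

    def test_dag_achieves_zero(self):
        ranks = min_agony_ranking(CHAIN)
        assert agony_of_ranking(CHAIN, ranks) == 0

    def test_two_cycle_minimum_is_two(self):
        # exhaustive: agony of a 2-cycle is max(0,d+1)+max(0,-d+1) >= 2 for any rank gap d
        g = GeneNetwork.from_edges([("a", "b"), ("b", "a")])
        assert agony_optimum(g.genes, g.edges) == 2
        assert agony_of_ranking(g, min_agony_ranking(g)) == 2

    @pytest.mark.parametrize("seed", range(30))
    def test_close_to_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        g = random_gene_network(n, int(rng.integers(1, n * (n - 1) + 1)), seed=seed)
        h = agony_of_ranking(g, min_agony_ranking(g))
        opt = agony_optimum(g.genes, g.edges)
        assert opt <= h <= max(opt, 1.5 * opt)


class TestEnsemble:
    def test_acyclic_untouched(self):
        assert remove_cycles_ensemble(CHAIN, seed=0).n_removed == 0

    def test_triangle_attains_optimum(self):
        res = remove_cycles_ensemble(TRIANGLE, seed=0)
        assert res.n_removed == 1 and is_dag(res.dag)

    @pytest.mark.parametrize("seed", range(25))
    def test_every_removed_edge_lay_on_a_cycle(self, seed):
        g = random_gene_network(int(5 + seed % 10), int(12 + seed % 14), seed=seed, ensure_cyclic=True)
        res = remove_cycles_ensemble(g, seed=seed)
        assert is_dag(res.dag)
        work = g.to_networkx()
        for u, v in res.removed_edges:
            sccs = [c for c in nx.strongly_connected_components(work) if len(c) > 1]
            assert any(u in c and v in c for c in sccs), f"{(u, v)} was not on a cycle when removed"
            work.remove_edge(u, v)


class TestAllMethods:
    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("seed", range(10))
    def test_partition_and_acyclicity(self, method, seed):
        g = random_gene_network(12, 30, seed=seed, ensure_cyclic=True, signed_fraction=0.4)
        res = convert(g, method, seed=seed)
        assert is_dag(res.dag)
        assert set(res.dag.edges) | set(res.removed_edges) == set(g.edges)
        assert set(res.dag.edges).isdisjoint(res.removed_edges)
        assert res.dag.genes == g.genes
        for e, s in res.dag.edges.items():
            assert s == g.edges[e]  # signs preserved

    @pytest.mark.parametrize("method", METHODS)
    def test_determinism(self, method):
        g = random_gene_network(15, 40, seed=99, ensure_cyclic=True)
        r1, r2 = convert(g, method, seed=5), convert(g, method, seed=5)
        assert r1.removed_edges == r2.removed_edges and r1.dag == r2.dag

    @pytest.mark.parametrize("seed", range(12))
    def test_no_method_beats_the_optimum(self, seed):
        rng = np.random.default_rng(seed)
        g = random_gene_network(4, int(rng.integers(3, 12)), seed=seed)
        opt = mfas_optimum(g.genes, g.edges)
        for method in METHODS:
            assert convert(g, method, seed=seed).n_removed >= opt
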