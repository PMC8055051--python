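"""Gene-network collapse, predicates and SIF/adjacency round trips."""

import pytest
from _oracles import collapse_oracle, random_hetero_graph

from kegg2net.kgml import HeteroGraph
from kegg2net.network import (
    ACTIVATING,
    INHIBITING,
    UNKNOWN,
    GeneNetwork,
    NetworkParseError,
    collapse_to_gene_network,
    has_cycle,
    nonisolated_count,
    parse_network,
    serialize_network,
)


def hg(kinds, edges):
    return HeteroGraph(kinds=dict(kinds), edges={e[:2]: (e[2] if len(e) > 2 else UNKNOWN) for e in edges})


class TestCollapse:
    def test_indirect_edge_through_compound(self):
        h = hg({"g1": "gene", "g2": "gene", "C": "compound"}, [("g1", "C", ACTIVATING), ("C", "g2", ACTIVATING)])
        net = collapse_to_gene_network(h)
        assert net.edges == {("g1", "g2"): ACTIVATING}

    def test_multi_hop_nongene_chain(self):
        h = hg(
            {"g1": "gene", "g2": "gene", "c1": "compound", "c2": "compound"},
            [("g1", "c1"), ("c1", "c2"), ("c2", "g2")],
        )
        assert set(collapse_to_gene_network(h).edges) == {("g1", "g2")}

    def test_gene_internal_node_blocks_indirect_edge(self):
        h = hg({"g1": "gene", "g2": "gene", "g3": "gene"}, [("g1", "g3"), ("g3", "g2")])
        assert set(collapse_to_gene_network(h).edges) == {("g1", "g3"), ("g3", "g2")}

    def test_self_loop_through_compound_suppressed(self):
        h = hg({"g1": "gene", "C": "compound"}, [("g1", "C"), ("C", "g1")])
        assert collapse_to_gene_network(h).edges == {}

    def test_sign_product_repression_of_repression(self):
        h = hg({"g1": "gene", "g2": "gene", "c": "compound"}, [("g1", "c", INHIBITING), ("c", "g2", INHIBITING)])
        assert collapse_to_gene_network(h).edges[("g1", "g2")] == ACTIVATING

    def test_disagreeing_paths_give_unknown_sign(self):
        h = hg(
            {"g1": "gene", "g2": "gene", "c1": "compound", "c2": "compound"},
            [("g1", "c1", ACTIVATING), ("c1", "g2", ACTIVATING), ("g1", "c2", INHIBITING), ("c2", "g2", ACTIVATING)],
        )
        assert collapse_to_gene_network(h).edges[("g1", "g2")] == UNKNOWN

    def test_gene_set_preserved_including_isolated(self):
        h = hg({"a": "gene", "b": "gene", "x": "map"}, [("a", "x")])
        assert collapse_to_gene_network(h).genes == ["a", "b"]

    @pytest.mark.parametrize("seed", range(60))
    def test_agrees_with_path_enumeration_oracle(self, seed):
        h = random_hetero_graph(seed, max_nodes=10)
        assert collapse_to_gene_network(h).edges == collapse_oracle(h)

    @pytest.mark.parametrize("seed", range(15))
    def test_idempotent_and_monotone(self, seed):
        h = random_hetero_graph(seed, max_nodes=10)
        net = collapse_to_gene_network(h)
        again = collapse_to_gene_network(HeteroGraph(kinds={g: "gene" for g in net.genes}, edges=dict(net.edges)))
        assert again == net
        # adding one edge to h never removes a collapsed edge
        nodes = sorted(h.kinds)
        if len(nodes) >= 2:
            u, v = nodes[0], nodes[-1]
            if u != v and (u, v) not in h.edges:
                h2 = HeteroGraph(kinds=dict(h.kinds), edges={**h.edges, (u, v): UNKNOWN})
                assert set(net.edges) <= set(collapse_to_gene_network(h2).edges)


class TestPredicates:
    def test_nonisolated_count(self):
        assert nonisolated_count(GeneNetwork([], {})) == 0
        net = GeneNetwork(["a", "b", "c"], {("a", "b"): UNKNOWN})
        assert nonisolated_count(net) == 2

    def test_nonisolated_count_matches_degree_enumeration(self):
        from kegg2net.fixtures import random_gene_network

        g = random_gene_network(10, 12, seed=4)
        by_degree = sum(1 for n in g.genes if any(n in e for e in g.edges))
        assert nonisolated_count(g) == by_degree

    def test_has_cycle(self):
        chain = GeneNetwork.from_edges([("a", "b"), ("b", "c")])
        assert not has_cycle(chain)
        tri = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        assert has_cycle(tri)
        two = GeneNetwork.from_edges([("a", "b"), ("b", "a"), ("c", "d")])
        assert has_cycle(two)

    def test_self_loops_rejected_at_construction(self):
        with pytest.raises(ValueError, match="self-loop"):
            GeneNetwork(["a"], {("a", "a"): UNKNOWN})


class TestSerialization:
    def test_sif_line_and_isolated_node(self):
        net = GeneNetwork(["a", "b", "z"], {("a", "b"): ACTIVATING})
        text = serialize_network(net, "sif")
        assert "a\tactivation\tb" in text.splitlines()
        assert "z" in text.splitlines()

    def test_adjacency_example(self):
        net = GeneNetwork(["a", "b"], {("a", "b"): UNKNOWN})
        assert serialize_network(net, "adjacency") == "\ta\tb\na\t0\t1\nb\t0\t0\n"

    def test_parse_sif_example(self):
        net = parse_network("a\tactivation\tb\n", "sif")
        assert net.edges == {("a", "b"): ACTIVATING} and set(net.genes) == {"a", "b"}

    def test_parse_adjacency_all_zero(self):
        net = parse_network("\ta\tb\tc\na\t0\t0\t0\nb\t0\t0\t0\nc\t0\t0\t0\n", "adjacency")
        assert net.genes == ["a", "b", "c"] and net.edges == {}

    @pytest.mark.parametrize("seed", range(50))
    def test_round_trip_both_formats(self, seed):
        from kegg2net.fixtures import random_gene_network

        g = random_gene_network(int(2 + seed % 8), int(seed % 12), seed=seed, signed_fraction=0.5)
        assert parse_network(serialize_network(g, "sif"), "sif") == g
        back = parse_network(serialize_network(g, "adjacency"), "adjacency")
        assert back.genes == g.genes and set(back.edges) == set(g.edges)  # adjacency carries no signs

    @pytest.mark.parametrize(
        "text,format,match",
        [
            ("a\tb\n", "sif", "line 1"),
            ("\ta\tb\na\t0\nb\t0\t0\n", "adjacency", "ragged"),
            ("\ta\tb\na\t0\t2\nb\t0\t0\n", "adjacency", "non-binary"),
        ],
    )
    def test_parse_errors_name_the_line(self, text, format, match):
        with pytest.raises(NetworkParseError, match=match):
            parse_network(text, format)

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="unsupported format"):
            serialize_network(GeneNetwork([], {}), "graphml")
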