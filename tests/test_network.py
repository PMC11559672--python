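"""Edge filtering, subnetwork induction, centralities and HBS labeling."""

import math

import networkx as nx
import numpy as np
import pytest

from cnanet.network import (
    ALL_CHANNELS,
    DEFAULT_CHANNELS,
    CentralityTable,
    EmptyNetworkError,
    InteractionRecord,
    Network,
    classify_hbs,
    compute_centralities,
    eigenvector_power_iteration,
    induce_network,
    load_interactions,
)


def edge_file(tmp_path, rows, channels=ALL_CHANNELS):
    p = tmp_path / "edges.txt"
    header = "protein1 protein2 " + " ".join(channels) + " combined_score"
    lines = [header]
    for a, b, scores in rows:
        vals = " ".join(str(scores.get(c, 0)) for c in channels)
        lines.append(f"{a} {b} {vals} 500")
    p.write_text("\n".join(lines) + "\n")
    return p


def record(a, b):
    return InteractionRecord(a, b, {c: 0 for c in ALL_CHANNELS})


def net_from_edges(edges, **kw):
    g = nx.Graph(edges)
    return Network(sample_id=kw.get("sample_id", "s"),
                   condition=kw.get("condition", "pre"), graph=g)


class TestLoadInteractions:
    def test_selected_channel_above_cutoff_kept(self, tmp_path):
        p = edge_file(tmp_path, [("A", "B", {"coexpression": 450})])
        assert len(load_interactions(p)) == 1

    def test_unselected_channel_never_qualifies(self, tmp_path):
        p = edge_file(tmp_path, [("A", "B", {"textmining": 900})])
        assert load_interactions(p) == []

    def test_below_cutoff_in_all_selected_dropped(self, tmp_path):
        p = edge_file(
            tmp_path, [("A", "B", {"coexpression": 399, "experiments": 399})]
        )
        assert load_interactions(p) == []

    def test_all_mode_requires_every_selected_channel(self, tmp_path):
        scores = {c: 450 for c in DEFAULT_CHANNELS}
        p = edge_file(tmp_path, [("A", "B", scores),
                                 ("C", "D", {"coexpression": 450})])
        kept = load_interactions(p, mode="all")
        assert [(r.node_a, r.node_b) for r in kept] == [("A", "B")]

    def test_unknown_channel_rejected_listing_valid_names(self, tmp_path):
        p = edge_file(tmp_path, [("A", "B", {"coexpression": 450})])
        with pytest.raises(ValueError, match="coexpression"):
            load_interactions(p, selected_channels={"bogus_channel"})

    def test_arbitrary_column_order_and_unknown_columns(self, tmp_path):
        p = tmp_path / "edges.txt"
        p.write_text(
            "mystery protein2 experiments protein1 coexpression\n"
            "7 B 0 A 880\n"
            "9 D 0 C 100\n"
        )
        kept = load_interactions(p, selected_channels={"coexpression",
                                                       "experiments"})
        assert [(r.node_a, r.node_b) for r in kept] == [("A", "B")]

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "edges.txt"
        p.write_text("protein1 protein2 coexpression\nA B oops\n")
        with pytest.raises(ValueError, match="line 2"):
            load_interactions(p, selected_channels={"coexpression"})


class TestInduceNetwork:
    def test_simplification_and_main_component(self):
        records = [record("A", "B"), record("B", "A"), record("C", "C")]
        net = induce_network({"A", "B", "C", "D"}, records)
        assert net.nodes == {"A", "B"}
        assert net.edges == {frozenset({"A", "B"})}

    def test_largest_component_retained(self):
        records = [record("A", "B"), record("B", "C"), record("A", "C"),
                   record("D", "E")]
        net = induce_network({"A", "B", "C", "D", "E"}, records)
        assert net.nodes == {"A", "B", "C"}

    def test_edge_with_endpoint_outside_set_dropped(self):
        records = [record("A", "B"), record("X", "Y")]
        net = induce_network({"A", "B", "Y"}, records)
        assert net.nodes == {"A", "B"}

    def test_tie_broken_by_smallest_symbol(self):
        records = [record("B", "C"), record("A", "D")]
        net = induce_network({"A", "B", "C", "D"}, records)
        assert net.nodes == {"A", "D"}

    def test_empty_induced_edges_raise(self):
        with pytest.raises(EmptyNetworkError, match="s9"):
            induce_network({"A", "B"}, [record("X", "Y")],
                           sample_id="s9", condition="post")


class TestCentralities:
    def test_path_graph(self):
        table = compute_centralities(net_from_edges([("A", "B"), ("B", "C")]))
        assert table.degree == {"A": 1, "B": 2, "C": 1}
        assert table.betweenness == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_graph(self):
        edges = [("c", leaf) for leaf in ("l1", "l2", "l3")]
        table = compute_centralities(net_from_edges(edges))
        assert table.betweenness["c"] == pytest.approx(3.0)  # 3 leaf pairs
        assert all(table.betweenness[l] == 0.0 for l in ("l1", "l2", "l3"))
        assert table.eigenvector["c"] == pytest.approx(1.0)
        for leaf in ("l1", "l2", "l3"):
            assert table.eigenvector[leaf] == pytest.approx(1 / math.sqrt(3),
                                                            abs=1e-8)

    def test_triangle_symmetry(self):
        table = compute_centralities(
            net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        )
        assert set(table.degree.values()) == {2}
        assert set(table.betweenness.values()) == {0.0}
        for v in table.nodes:
            assert table.eigenvector[v] == pytest.approx(1.0, abs=1e-9)

    def test_degree_sum_is_twice_edges_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0 or not nx.is_connected(g):
                continue
            net = Network("s", "pre", g)
            table = compute_centralities(net)
            assert sum(table.degree.values()) == 2 * g.number_of_edges()
            assert all(b >= 0 for b in table.betweenness.values())
            for v in g.nodes:
                if g.degree(v) == 1:
                    assert table.betweenness[v] == 0.0

    def test_betweenness_cross_checked_against_networkx(self):
        # independent library route; the from-scratch oracle lives in the
        # acceptance suite
        rng = np.random.default_rng(11)
        for _ in range(30):
            g = nx.gnp_random_graph(9, 0.35, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            table = compute_centralities(Network("s", "pre", g))
            ref = nx.betweenness_centrality(g, normalized=False)
            for v in g.nodes:
                assert table.betweenness[v] == pytest.approx(ref[v], abs=1e-9)

    def test_eigenvector_matches_dense_eigendecomposition(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        assert nx.is_connected(g)
        a = nx.to_numpy_array(g)
        vec = eigenvector_power_iteration(a)
        w, v = np.linalg.eigh(a)
        principal = np.abs(v[:, np.argmax(w)])
        principal /= principal.max()
        assert np.max(np.abs(vec - principal)) < 1e-8

    def test_power_iteration_converges_on_bipartite_graph(self):
        # path P4 is bipartite; the A+I shift must suppress oscillation
        a = nx.to_numpy_array(nx.path_graph(4))
        vec = eigenvector_power_iteration(a)
        assert vec.max() == pytest.approx(1.0)

    def test_adding_edge_never_decreases_endpoint_degree(self):
        g = nx.gnp_random_graph(8, 0.4, seed=3)
        assert nx.is_connected(g)
        before = compute_centralities(Network("s", "pre", g)).degree
        missing = [
            (u, v) for u in g.nodes for v in g.nodes
            if u < v and not g.has_edge(u, v)
        ]
        g2 = g.copy()
        g2.add_edge(*missing[0])
        after = compute_centralities(Network("s", "pre", g2)).degree
        u, v = missing[0]
        assert after[u] >= before[u] and after[v] >= before[v]


class TestHBS:
    def test_vertex_transitive_graphs_have_no_labels(self):
        for g in (nx.complete_graph(3), nx.cycle_graph(5),
                  nx.complete_graph(5), nx.petersen_graph()):
            labels = classify_hbs(compute_centralities(Network("s", "pre", g)))
            assert labels.hubs == frozenset()
            assert labels.bottlenecks == frozenset()
            assert labels.switches == frozenset()
            assert labels.hbs == frozenset()

    def test_star_center_is_unique_hbs(self):
        g = nx.star_graph(3)  # center 0, mean degree 6/4 = 1.5
        labels = classify_hbs(compute_centralities(Network("s", "pre", g)))
        assert labels.mean_degree == pytest.approx(1.5)
        assert labels.hbs == {0}

    def test_hub_alone_is_not_hbs(self):
        table = CentralityTable(
            sample_id="s", condition="pre", nodes=("a", "b"),
            degree={"a": 5, "b": 1},
            betweenness={"a": 1.0, "b": 1.0},
            eigenvector={"a": 0.5, "b": 0.5},
        )
        labels = classify_hbs(table)
        assert labels.is_hub["a"] and not labels.is_hbs["a"]

    def test_hbs_is_conjunction_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            labels = classify_hbs(compute_centralities(Network("s", "pre", g)))
            assert labels.hbs == labels.hubs & labels.bottlenecks & labels.switches
            assert len(labels.hbs) <= min(
                len(labels.hubs), len(labels.bottlenecks), len(labels.switches)
            )
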