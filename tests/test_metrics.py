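"""Network metrics: connectance, mean degree, degree skewness, modularity
and the divisive edge-betweenness community search."""

import networkx as nx
import numpy as np
import pytest

from paleonet import (
    CoNetwork, UsageError, connectance, degree_skewness, girvan_newman,
    mean_degree, modularity, network_summary,
)
from paleonet.metrics import girvan_newman_cuts, round_metrics_table, metrics_table


def _gnm(s: int, l: int, seed: int = 0) -> nx.Graph:
    return nx.gnm_random_graph(s, l, seed=seed)


class TestConnectanceMeanDegree:
    @pytest.mark.parametrize(
        "s,l,conn,md",
        [
            (43, 73, 0.081, 3.40),   # low impact, pre-industrial
            (44, 74, 0.078, 3.36),   # low impact, modern
            (38, 60, 0.085, 3.16),   # high impact, pre-industrial
            (27, 27, 0.077, 2.00),   # high impact, modern
            (13, 11, 0.141, 1.69),   # St-Damase zone 1
            (18, 25, 0.163, 2.78),   # Michaud zone 1
        ],
    )
    def test_reported_table_values(self, s, l, conn, md):
        g = _gnm(s, l)
        assert round(connectance(g), 3) == pytest.approx(conn)
        assert round(mean_degree(g), 2) == pytest.approx(md)

    def test_complete_graph_connectance_one(self):
        assert connectance(nx.complete_graph(2)) == 1.0
        assert connectance(nx.complete_graph(7)) == 1.0

    def test_regular_graph_mean_degree(self):
        assert mean_degree(nx.cycle_graph(9)) == 2.0

    def test_mean_degree_is_degree_sum_identity(self):
        g = _gnm(20, 40, seed=3)
        degs = [d for _, d in g.degree()]
        assert mean_degree(g) == pytest.approx(np.sum(degs) / 20)
        assert np.sum(degs) == 2 * g.number_of_edges()

    def test_connectance_needs_two_nodes(self):
        with pytest.raises(UsageError):
            connectance(nx.empty_graph(1))


class TestDegreeSkewness:
    def test_regular_graph_zero(self):
        assert degree_skewness(nx.cycle_graph(8)) == 0.0

    def test_symmetric_degrees_zero(self):
        assert degree_skewness([1, 2, 3]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # degrees (0,0,6): third central moment 48, sample sd sqrt(12)
        assert degree_skewness([0, 0, 6]) == pytest.approx(48 / (2 * 12 ** 1.5))
        assert degree_skewness([0, 0, 6]) == pytest.approx(0.57735, abs=1e-5)

    def test_moment_ratio_variant_differs_for_small_n(self):
        d = [0, 0, 6]
        m = np.asarray(d, dtype=float)
        m3 = ((m - m.mean()) ** 3).mean()
        m2 = ((m - m.mean()) ** 2).mean()
        assert degree_skewness(d, method="moment") == pytest.approx(m3 / m2 ** 1.5)
        assert degree_skewness(d, method="moment") != pytest.approx(
            degree_skewness(d, method="sample"))


class TestModularity:
    def test_trivial_partition_zero_for_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g = nx.gnp_random_graph(int(rng.integers(3, 15)),
                                    rng.uniform(0.2, 0.9),
                                    seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            assert modularity(g, [set(g.nodes)]) == pytest.approx(0.0, abs=1e-12)

    def test_single_edge_singletons_minus_half(self):
        g = nx.Graph([(0, 1)])
        assert modularity(g, [{0}, {1}]) == pytest.approx(-0.5)

    def test_two_disjoint_cliques_half(self):
        for m in (3, 4, 6):
            g = nx.disjoint_union(nx.complete_graph(m), nx.complete_graph(m))
            part = [set(range(m)), set(range(m, 2 * m))]
            assert modularity(g, part) == pytest.approx(0.5)

    def test_matches_networkx(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            g = nx.gnp_random_graph(10, 0.4, seed=trial)
            if g.number_of_edges() == 0:
                continue
            labels = rng.integers(0, 3, 10)
            comms = [set(np.flatnonzero(labels == k)) for k in range(3)
                     if (labels == k).any()]
            assert modularity(g, comms) == pytest.approx(
                nx.community.modularity(g, comms), abs=1e-12)

    def test_edgeless_graph_undefined(self):
        with pytest.raises(UsageError):
            modularity(nx.empty_graph(4), [set(range(4))])


class TestGirvanNewman:
    def test_two_triangles_split_into_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g.add_edge(2, 3)  # bridge
        part = girvan_newman(g)
        assert sorted(sorted(c) for c in part.communities) == [[0, 1, 2], [3, 4, 5]]

    def test_single_edge_stays_one_community(self):
        # Q=0 for the joint community beats Q=-0.5 for singletons
        part = girvan_newman(nx.Graph([("a", "b")]))
        assert part.n_communities == 1

    def test_never_merges_disconnected_components(self):
        g = nx.disjoint_union(nx.cycle_graph(4), nx.path_graph(3))
        part = girvan_newman(g)
        comp_sets = [frozenset(c) for c in nx.connected_components(g)]
        for community in part.communities:
            assert any(community <= comp for comp in comp_sets)

    def test_max_q_over_dendrogram_cuts_small_graphs(self):
        # independent oracle: networkx's divisive dendrogram + networkx
        # modularity, maximised over every cut
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 30:
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, rng.uniform(0.25, 0.7),
                                    seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            q_mine = modularity(g, girvan_newman(g))
            cuts = [[frozenset(c) for c in nx.connected_components(g)]]
            cuts += [[frozenset(c) for c in cut]
                     for cut in nx.community.girvan_newman(g)]
            q_oracle = max(nx.community.modularity(g, c) for c in cuts)
            assert q_mine == pytest.approx(q_oracle, abs=1e-9)
            checked += 1

    def test_edgeless_graph_all_singletons(self):
        part = girvan_newman(nx.empty_graph(5))
        assert part.n_communities == 5

    def test_deterministic_across_runs(self):
        g = nx.gnp_random_graph(12, 0.3, seed=4)
        a = girvan_newman(g).communities
        b = girvan_newman(g).communities
        assert a == b

    def test_cut_sequence_starts_at_components(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        cuts = girvan_newman_cuts(g)
        assert len(cuts[0]) == 2
        assert len(cuts[-1]) == 6


class TestNetworkSummary:
    def test_empty_graph_flags(self):
        m = network_summary(nx.empty_graph(5))
        assert m.connectance == 0.0
        assert m.mean_degree == 0.0
        assert m.modularity is None
        assert "modularity_undefined" in m.flags
        assert m.skewness == 0.0

    def test_regular_ring_like_network(self):
        # a 27-node 2-regular topology: mean degree 2.00, skewness 0
        m = network_summary(nx.cycle_graph(27))
        assert m.S == 27 and m.L == 27
        assert m.mean_degree == pytest.approx(2.0)
        assert m.skewness == 0.0
        assert round(m.connectance, 3) == 0.077

    def test_summary_counts_match_builder(self):
        g = _gnm(15, 30, seed=9)
        m = network_summary(CoNetwork(graph=g))
        assert (m.S, m.L) == (15, 30)

    def test_rounding_matches_report_precision(self):
        tab = metrics_table({"x": network_summary(_gnm(43, 73, seed=1))})
        out = round_metrics_table(tab)
        assert out.loc[0, "connectance"] == 0.081
        assert out.loc[0, "mean_degree"] == 3.40
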