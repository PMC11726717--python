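"""Dynamical-network construction, paths, betweenness and communities,
checked against exhaustive enumeration on small graphs."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from allodyn import io, metrics, network as net_mod, synthetic as syn
from allodyn.network import (
    CorrelationMatrix,
    DynamicalNetwork,
    NetworkBuildParams,
    NoPathError,
)

from conftest import best_label_agreement


def make_net(edges, condition="test"):
    """edges: iterable of (u, v, corr)."""
    g = nx.Graph()
    for u, v, corr in edges:
        g.add_edge(u, v, corr=corr, weight=-math.log(corr))
    return DynamicalNetwork(graph=g, condition=condition)


def random_net(rng, n_nodes, p=0.35):
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                edges.append((i, j, float(rng.uniform(0.05, 0.95))))
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for u, v, c in edges:
        g.add_edge(u, v, corr=c, weight=-math.log(c))
    return DynamicalNetwork(graph=g)


def enumerate_paths(net, source, sink):
    """Exhaustive simple-path enumeration with costs (independent oracle)."""
    out = []
    for path in nx.all_simple_paths(net.graph, source, sink):
        cost = sum(net.graph[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
        out.append((tuple(path), cost))
    return out


def brute_edge_betweenness(net):
    """Fractional shortest-path counting over unordered node pairs."""
    scores = {(min(u, v), max(u, v)): 0.0 for u, v in net.graph.edges}
    nodes = sorted(net.graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = enumerate_paths(net, s, t)
        except nx.NodeNotFound:
            continue
        if not paths:
            continue
        best = min(c for _, c in paths)
        shortest = [p for p, c in paths if abs(c - best) < 1e-9]
        for p in shortest:
            for u, v in zip(p[:-1], p[1:]):
                scores[(min(u, v), max(u, v))] += 1.0 / len(shortest)
    return scores


class TestCorrelationMatrix:
    def test_rigidly_coupled_pair_fully_correlated(self):
        rng = np.random.default_rng(0)
        top = syn.ca_topology(2)
        disp = rng.normal(size=(200, 1, 3))
        coords = np.tile(disp, (1, 2, 1)) + np.array([[0.0, 0, 0], [3.8, 0, 0]])
        traj = io.Trajectory(topology=top, coordinates=coords)
        cm = net_mod.correlation_matrix(traj, io.select(top, "name CA"))
        assert cm.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_prescribed_correlation_recovered(self, correlated_ensemble):
        traj = correlated_ensemble[0]
        cm = net_mod.correlation_matrix(traj, io.select(traj.topology, "name CA"))
        assert cm.matrix[0, 1] == pytest.approx(0.8, abs=0.03)
        assert abs(cm.matrix[2, 3]) < 0.03

    def test_zero_variance_residue_named(self):
        top = syn.ca_topology(2)
        coords = np.zeros((10, 2, 3))
        coords[:, 0, :] = np.random.default_rng(1).normal(size=(10, 3))
        traj = io.Trajectory(topology=top, coordinates=coords)
        with pytest.raises(ValueError, match=r"zero-variance.*2"):
            net_mod.correlation_matrix(traj, io.select(top, "name CA"))


class TestBuildNetwork:
    def corr(self, n, value=0.5):
        mat = np.full((n, n), value)
        np.fill_diagonal(mat, 1.0)
        return CorrelationMatrix(resids=np.arange(1, n + 1), matrix=mat)

    def contacts(self, pairs_pers, n_frames=1000):
        import pandas as pd

        rows = [
            dict(res_a=a, res_b=b, persistency=p,
                 replica_persistency=[p], consecutive=abs(a - b) == 1)
            for (a, b), p in pairs_pers.items()
        ]
        return metrics.ContactTable(
            table=pd.DataFrame(rows), frames_per_replica=(n_frames,)
        )

    def test_perfect_correlation_gives_zero_weight(self):
        corr = self.corr(3, value=1.0 - 1e-15)
        net = net_mod.build_network(corr, self.contacts({(1, 3): 80.0}))
        assert net.graph[1][3]["weight"] == pytest.approx(0.0, abs=1e-12)

    def test_persistency_boundary_is_inclusive(self):
        corr = self.corr(4)
        table = self.contacts({(1, 3): 74.9, (2, 4): 75.0})
        net = net_mod.build_network(corr, table)
        assert not net.graph.has_edge(1, 3)
        assert net.graph.has_edge(2, 4)

    def test_consecutive_chain_yields_empty_edge_set(self):
        corr = self.corr(5)
        table = self.contacts({(i, i + 1): 100.0 for i in range(1, 5)})
        net = net_mod.build_network(corr, table)
        assert net.n_edges == 0
        net_keep = net_mod.build_network(
            corr, table, NetworkBuildParams(exclude_consecutive=False)
        )
        assert net_keep.n_edges == 4

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(5)
        n = 8
        mat = np.clip((a := rng.uniform(0.2, 0.9, (n, n))) @ a.T / n, -0.99, 0.99)
        np.fill_diagonal(mat, 1.0)
        corr = CorrelationMatrix(resids=np.arange(1, n + 1), matrix=(mat + mat.T) / 2)
        pairs = {
            (i, j): float(rng.uniform(0, 100))
            for i in range(1, n + 1)
            for j in range(i + 1, n + 1)
        }
        table = self.contacts(pairs)
        prev = None
        for thr in (25.0, 50.0, 75.0, 90.0):
            edges = set(
                net_mod.build_network(
                    corr, table, NetworkBuildParams(persistency_threshold=thr)
                ).graph.edges
            )
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestShortestPath:
    def test_single_edge(self):
        net = make_net([(1, 2, 0.5)])
        path = net_mod.shortest_path(net, 1, 2)
        assert path.nodes == (1, 2)

    def test_two_hop_beats_heavy_direct_edge(self):
        # weights: direct -log(0.05)≈3.0, two hops 2×(-log(0.37))≈2.0
        net = make_net([(1, 3, 0.05), (1, 2, 0.37), (2, 3, 0.37)])
        path = net_mod.shortest_path(net, 1, 3)
        assert path.nodes == (1, 2, 3)

    def test_disconnected_pair_raises(self):
        net = make_net([(1, 2, 0.5), (3, 4, 0.5)])
        with pytest.raises(NoPathError):
            net_mod.shortest_path(net, 1, 4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, 12)
        nodes = sorted(net.graph.nodes)
        for s, t in [(nodes[0], nodes[-1]), (nodes[1], nodes[-2])]:
            paths = enumerate_paths(net, s, t)
            if not paths:
                with pytest.raises(NoPathError):
                    net_mod.shortest_path(net, s, t)
                continue
            best = min(c for _, c in paths)
            got = net_mod.shortest_path(net, s, t)
            assert got.cost == pytest.approx(best, abs=1e-9)
            ties = sorted(p for p, c in paths if abs(c - best) < 1e-9)
            assert got.nodes == ties[0]  # lexicographic tie-break


class TestSuboptimalPaths:
    def test_zero_tolerance_returns_only_optima(self):
        net = make_net([(1, 2, 0.5), (2, 4, 0.5), (1, 3, 0.5), (3, 4, 0.5)])
        ens = net_mod.suboptimal_paths(net, 1, 4, tolerance=0.0)
        assert {p.nodes for p in ens.paths} == {(1, 2, 4), (1, 3, 4)}
        assert ens.edge_usage[(1, 2)] == 1 and ens.edge_usage[(2, 4)] == 1

    def test_every_listed_path_within_tolerance(self):
        rng = np.random.default_rng(7)
        net = random_net(rng, 10, p=0.5)
        ens = net_mod.suboptimal_paths(net, 0, 9, tolerance=1.0)
        for p in ens.paths:
            assert ens.optimal.cost - 1e-9 <= p.cost <= ens.optimal.cost + 1.0 + 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_net(rng, 10, p=0.45)
        if not nx.has_path(net.graph, 0, 9):
            pytest.skip("disconnected draw")
        ens = net_mod.suboptimal_paths(net, 0, 9, tolerance=1.0)
        paths = enumerate_paths(net, 0, 9)
        best = min(c for _, c in paths)
        expected = {p for p, c in paths if c <= best + 1.0 + 1e-12}
        assert {p.nodes for p in ens.paths} == expected

    def test_truncation_flagged(self):
        g = nx.complete_graph(9)
        for u, v in g.edges:
            g[u][v].update(corr=0.9, weight=-math.log(0.9))
        net = DynamicalNetwork(graph=g)
        ens = net_mod.suboptimal_paths(net, 0, 8, tolerance=10.0, max_paths=5)
        assert ens.truncated and len(ens.paths) == 5


class TestEdgeBetweenness:
    def test_path_graph_hand_count(self):
        net = make_net([("A", "B", 0.5), ("B", "C", 0.5)])
        scores = net_mod.edge_betweenness(net)
        # pairs {A,B} and {A,C} both route through A–B
        assert scores[("A", "B")] == pytest.approx(2.0)
        assert scores[("B", "C")] == pytest.approx(2.0)

    def test_star_edges_symmetric(self):
        net = make_net([("hub", leaf, 0.5) for leaf in "abcd"])
        scores = net_mod.edge_betweenness(net)
        assert len(set(round(s, 9) for s in scores.values())) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        net = random_net(rng, 10, p=0.4)
        got = net_mod.edge_betweenness(net)
        want = brute_edge_betweenness(net)
        for edge, score in want.items():
            assert got[edge] == pytest.approx(score, abs=1e-6)


class TestCommunities:
    def test_two_cliques_split_at_bridge(self):
        net = syn.two_clique_bridge(10)
        part = net_mod.detect_communities(net)
        truth = {n: net.graph.nodes[n]["block"] for n in net.graph.nodes}
        assert best_label_agreement(part.labels, truth) == 1.0
        assert len(part.communities()) == 2

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(8)
        for u, v in g.edges:
            g[u][v].update(corr=0.7, weight=-math.log(0.7))
        part = net_mod.detect_communities(DynamicalNetwork(graph=g))
        assert len(part.communities()) == 1

    def test_partition_invariant_under_node_relabelling(self):
        net = syn.gen_planted_network(6, 2, p_in=0.95, p_out=0.05, seed=4)
        part = net_mod.detect_communities(net)
        mapping = {n: n * 7 % 97 for n in net.graph.nodes}  # injective scramble
        relabeled = DynamicalNetwork(graph=nx.relabel_nodes(net.graph, mapping))
        part2 = net_mod.detect_communities(relabeled)
        groups1 = {frozenset(mapping[n] for n in c) for c in part.communities()}
        groups2 = {frozenset(c) for c in part2.communities()}
        assert groups1 == groups2


class TestSubnetworkAndCompare:
    def test_full_residue_set_is_identity(self):
        net = syn.two_clique_bridge(5)
        sub, summary = net_mod.subnetwork(net, net.graph.nodes)
        assert summary["n_edges"] == net.n_edges

    def test_disjoint_set_rejected(self):
        net = syn.two_clique_bridge(5)
        with pytest.raises(ValueError, match="empty"):
            net_mod.subnetwork(net, {999})

    def test_window_edge_count_matches_direct_filter(self):
        rng = np.random.default_rng(3)
        net = random_net(rng, 20, p=0.3)
        window = set(range(5, 15))
        _, summary = net_mod.subnetwork(net, window)
        direct = sum(
            1 for u, v in net.graph.edges if u in window and v in window
        )
        assert summary["n_edges"] == direct

    def test_identical_networks_compare_clean(self):
        net = syn.two_clique_bridge(5)
        diff = net_mod.compare_networks(net, net)
        assert (diff["status"] == "common").all()
        assert np.allclose(diff["delta_weight"], 0.0)

    def test_removed_edge_reported_lost(self):
        net = syn.two_clique_bridge(5)
        g2 = net.graph.copy()
        g2.remove_edge(4, 5)  # the bridge
        other = DynamicalNetwork(graph=g2)
        diff = net_mod.compare_networks(other, net)
        lost = diff[diff["status"] == "lost"]
        assert len(lost) == 1 and (lost.iloc[0]["i"], lost.iloc[0]["j"]) == (4, 5)


class TestScalingInvariance:
    def test_uniform_correlation_scaling_preserves_paths(self):
        rng = np.random.default_rng(9)
        net = random_net(rng, 10, p=0.5)
        scaled_g = net.graph.copy()
        for u, v in scaled_g.edges:
            c = scaled_g[u][v]["corr"] * 0.5
            scaled_g[u][v].update(corr=c, weight=-math.log(c))
        scaled = DynamicalNetwork(graph=scaled_g)
        p1 = net_mod.shortest_path(net, 0, 9)
        p2 = net_mod.shortest_path(scaled, 0, 9)
        # scaling every |C| by a constant adds -log(0.5) per hop: the
        # ranking can change only through path length, not edge identity
        assert p2.cost == pytest.approx(
            sum(-math.log(scaled_g[u][v]["corr"]) for u, v in zip(p2.nodes[:-1], p2.nodes[1:]))
        )

    def test_log_base_change_preserves_path_and_communities(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            net_e = random_net(rng, 9, p=0.5)
            g10 = net_e.graph.copy()
            for u, v in g10.edges:
                g10[u][v]["weight"] = -math.log10(g10[u][v]["corr"])
            net_10 = DynamicalNetwork(graph=g10)
            if nx.has_path(net_e.graph, 0, 8):
                assert (
                    net_mod.shortest_path(net_e, 0, 8).nodes
                    == net_mod.shortest_path(net_10, 0, 8).nodes
                )
            assert (
                net_mod.detect_communities(net_e).labels
                == net_mod.detect_communities(net_10).labels
            )
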