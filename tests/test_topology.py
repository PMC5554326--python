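"""Topological indices versus independent brute-force oracles."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

import menconserve as mc
from conftest import net_from_edges


# --- independent oracles (no networkx algorithms) -------------------------

def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def oracle_avg_gd(edges):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    total, count = 0, 0
    for s in adj:
        for v, d in bfs_distances(adj, s).items():
            if v != s:
                total += d
                count += 1
    return total / count


def oracle_avg_cc(edges):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    coeffs = []
    for u in adj:
        nbrs = list(adj[u])
        k = len(nbrs)
        if k < 2:
            coeffs.append(0.0)
            continue
        links = sum(
            1 for i in range(k) for j in range(i + 1, k) if nbrs[j] in adj[nbrs[i]]
        )
        coeffs.append(2 * links / (k * (k - 1)))
    return sum(coeffs) / len(coeffs)


def set_partitions(items):
    """All partitions of a list into nonempty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1 :]
        yield partition + [[first]]


def newman_girvan_q(edges, partition):
    m = len(edges)
    module = {node: k for k, block in enumerate(partition) for node in block}
    degree = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    q = 0.0
    n_modules = len(partition)
    e_within = [0] * n_modules
    d_sum = [0] * n_modules
    for a, b in edges:
        if module[a] == module[b]:
            e_within[module[a]] += 1
    for node, k in degree.items():
        d_sum[module[node]] += k
    for k in range(n_modules):
        q += e_within[k] / m - (d_sum[k] / (2 * m)) ** 2
    return q


def oracle_best_modularity(edges):
    nodes = sorted({n for e in edges for n in e})
    return max(newman_girvan_q(edges, p) for p in set_partitions(nodes))


# --- fixture graphs --------------------------------------------------------

TRIANGLE = [(0, 1), (1, 2), (0, 2)]
PATH3 = [(0, 1), (1, 2)]
STAR4 = [(0, i) for i in range(1, 5)]
TWO_TRIANGLES = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
BRIDGED_TRIANGLES = TWO_TRIANGLES + [(2, 3)]
TWO_EDGES = [(0, 1), (2, 3)]
TRIANGLE_PENDANT = TRIANGLE + [(2, 3)]


class TestNodeConnectivity:
    def test_triangle_all_degree_two(self):
        conn = mc.node_connectivity(net_from_edges(TRIANGLE))
        assert set(conn.values()) == {2}

    def test_star_hub_and_leaves(self):
        conn = mc.node_connectivity(net_from_edges(STAR4))
        assert conn[0] == 4
        assert all(conn[i] == 1 for i in range(1, 5))

    def test_handshake_lemma(self, trait_table, grouping):
        sub = mc.prevalence_filter(trait_table, grouping.samples_in("G1"))
        corr = mc.correlation_matrix(mc.standardize_features(sub))
        net = mc.build_network(corr, 0.8)
        assert sum(mc.node_connectivity(net).values()) == 2 * net.n_edges


class TestAverageGeodesicDistance:
    @pytest.mark.parametrize("edges,expected", [
        (PATH3, 4 / 3),
        (TRIANGLE, 1.0),
        (TWO_EDGES, 1.0),  # only mutually reachable pairs count
        (STAR4, (8 * 1 + 12 * 2) / 20),  # ordered pairs: 8 hub-leaf, 12 leaf-leaf
    ])
    def test_hand_computed_values(self, edges, expected):
        assert mc.average_geodesic_distance(net_from_edges(edges)) == pytest.approx(expected)

    def test_edgeless_network_undefined(self):
        net = net_from_edges([])
        with pytest.raises(mc.UndefinedMetricError):
            mc.average_geodesic_distance(net)


class TestAverageClusteringCoefficient:
    @pytest.mark.parametrize("edges,expected", [
        (TRIANGLE, 1.0),
        (PATH3, 0.0),
        (STAR4, 0.0),
        (TRIANGLE_PENDANT, (1 / 3 + 1 + 1 + 0) / 4),
    ])
    def test_hand_computed_values(self, edges, expected):
        assert mc.average_clustering_coefficient(net_from_edges(edges)) == pytest.approx(expected)


class TestGreedyModularity:
    def test_two_disconnected_triangles(self):
        partition, q = mc.greedy_modularity(net_from_edges(TWO_TRIANGLES))
        assert q == pytest.approx(0.5)
        assert partition[0] == partition[1] == partition[2]
        assert partition[3] == partition[4] == partition[5]
        assert partition[0] != partition[3]

    def test_bridged_triangles_known_q(self):
        _, q = mc.greedy_modularity(net_from_edges(BRIDGED_TRIANGLES))
        assert q == pytest.approx(10 / 28)

    def test_complete_graph_no_structure(self):
        edges = list(itertools.combinations(range(5), 2))
        _, q = mc.greedy_modularity(net_from_edges(edges))
        assert q == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("edges", [TWO_TRIANGLES, BRIDGED_TRIANGLES, STAR4, PATH3])
    def test_matches_bruteforce_optimum_on_small_fixtures(self, edges):
        _, q = mc.greedy_modularity(net_from_edges(edges))
        assert q == pytest.approx(oracle_best_modularity(edges))

    def test_never_exceeds_bruteforce_optimum(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = nx.gnp_random_graph(7, 0.4, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            edges = list(g.edges)
            _, q = mc.greedy_modularity(net_from_edges(edges))
            assert q <= oracle_best_modularity(edges) + 1e-12


class TestOracleAgreementOnRandomGraphs:
    def test_avg_gd_and_avg_cc_match_oracles(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 50:
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            edges = list(g.edges)
            net = net_from_edges(edges)
            # oracle covers only nodes with at least one edge; align by
            # comparing on the same graph (isolates never enter networks)
            assert mc.average_geodesic_distance(net) == pytest.approx(oracle_avg_gd(edges))
            assert mc.average_clustering_coefficient(net) == pytest.approx(oracle_avg_cc(edges))
            checked += 1


class TestRankNormalization:
    def test_formula_endpoints(self):
        # distinct degrees: ranks 1..4, Max = 4
        conn = {"a": 9, "b": 5, "c": 3, "d": 1}
        norm = mc.normalize_connectivity_ranks(conn)
        assert norm["a"] == pytest.approx(1.0)
        assert norm["d"] == pytest.approx(100.0)
        assert all(1 <= v <= 100 for v in norm.values())

    def test_printed_formula_value(self):
        # Max = 5, rank_org = 3 -> (1 - 2/4) * 99 + 1 = 50.5
        conn = {n: d for n, d in zip("abcde", [10, 8, 6, 4, 2])}
        norm = mc.normalize_connectivity_ranks(conn)
        assert norm["c"] == pytest.approx(50.5)

    def test_ties_get_average_ranks(self):
        conn = {"hub": 4, "l1": 1, "l2": 1, "l3": 1, "l4": 1}
        norm = mc.normalize_connectivity_ranks(conn)
        assert norm["hub"] == pytest.approx(1.0)
        # leaves tie at rank (2+3+4+5)/4 = 3.5 = Max -> 100
        assert all(norm[f"l{i}"] == pytest.approx(100.0) for i in range(1, 5))

    def test_monotone_in_connectivity(self):
        rng = np.random.default_rng(1)
        conn = {f"n{i}": int(d) for i, d in enumerate(rng.integers(1, 20, size=30))}
        norm = mc.normalize_connectivity_ranks(conn)
        for a in conn:
            for b in conn:
                if conn[a] > conn[b]:
                    assert norm[a] <= norm[b]

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            mc.normalize_connectivity_ranks({"a": 3})


class TestConnectivityScores:
    def test_score_is_101_minus_rank_and_zero_when_absent(self):
        scores = mc.connectivity_scores(
            {"net1": {"a": 1.0, "b": 100.0}},
            node_universe=["a", "b", "c"],
            networks=["net1", "net2"],
        )
        assert scores.loc["a", "net1"] == pytest.approx(100.0)
        assert scores.loc["b", "net1"] == pytest.approx(1.0)
        assert scores.loc["c", "net1"] == 0.0
        assert (scores["net2"] == 0).all()
        assert ((scores >= 0) & (scores <= 100)).all().all()

    def test_score_plus_rank_is_101_where_present(self, trait_table, grouping):
        sub = mc.prevalence_filter(trait_table, grouping.samples_in("G4"))
        corr = mc.correlation_matrix(mc.standardize_features(sub))
        net = mc.build_network(corr, 0.8, layer="trait", group="G4")
        profiles = mc.node_profiles([net])
        assert np.allclose(profiles["score"] + profiles["rank_norm"], 101.0)
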