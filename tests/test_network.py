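import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fringescope.data_model import ASVTable, GeochemTable
from fringescope.network import (
    CooccurrenceNetwork,
    build_network,
    filter_asvs,
    louvain,
    node_geochem_correlation,
    partition_modularity,
    spearman_rho,
)


def _table(arr, normalized=False):
    arr = np.asarray(arr)
    return ASVTable(
        pd.DataFrame(arr, index=[f"A{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        normalized=normalized)


class TestFilter:
    def test_21_reads_4_sites_kept(self):
        t = _table([[6, 5, 5, 5, 0]])
        assert filter_asvs(t).asv_ids == ["A0"]

    def test_total_exactly_20_removed(self):
        t = _table([[4, 4, 4, 4, 4]])            # 20 reads, 5 sites
        with pytest.warns(UserWarning):
            out = filter_asvs(t)
        assert out.asv_ids == []

    def test_exactly_3_sites_removed(self):
        t = _table([[40, 40, 20, 0, 0]])         # 100 reads, 3 sites
        with pytest.warns(UserWarning):
            out = filter_asvs(t)
        assert out.asv_ids == []

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        t = _table(rng.integers(0, 15, size=(12, 6)))
        once = filter_asvs(t)
        twice = filter_asvs(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestSpearman:
    def test_monotone_transform_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(x, x ** 3) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_midrank_tie_value(self):
        # Pearson on midranks (1, 2.5, 2.5, 4) vs (1, 3, 2, 4) = 0.948683
        rho = spearman_rho([1, 2, 2, 3], [1, 3, 2, 4])
        assert rho == pytest.approx(4.5 / np.sqrt(22.5), rel=1e-12)

    def test_constant_vector_is_nan(self):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


class TestBuildNetwork:
    def test_perfect_covariation_single_edge(self):
        t = _table([[1, 2, 3, 4], [2, 4, 6, 8]], normalized=True)
        net = build_network(t)
        assert len(net.edges) == 1
        assert net.edges[0][2] == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        # rho(A0, A1) is exactly 0.5; a threshold of 0.5 must give no edge
        t = _table([[1, 2, 3], [1, 3, 2]], normalized=True)
        assert len(build_network(t, rho_threshold=0.5).edges) == 0
        assert len(build_network(t, rho_threshold=0.499).edges) == 1

    def test_signed_rule_ignores_negative_unless_absolute(self):
        t = _table([[1, 2, 3, 4], [4, 3, 2, 1]], normalized=True)
        assert len(build_network(t, rho_threshold=0.7).edges) == 0
        net = build_network(t, rho_threshold=0.7, absolute=True)
        assert len(net.edges) == 1 and net.edges[0][2] == pytest.approx(-1.0)

    def test_null_edge_density_low(self):
        rng = np.random.default_rng(42)
        t = _table(rng.random((20, 46)), normalized=True)
        net = build_network(t)
        assert len(net.edges) / (20 * 19 / 2) < 0.05

    def test_isolated_nodes_retained(self):
        t = _table([[1, 2, 3, 4], [2, 4, 6, 8], [5, 1, 4, 2]], normalized=True)
        net = build_network(t)
        assert set(net.nodes) == {"A0", "A1", "A2"}


def _net_from_edges(n, edges):
    nodes = [f"n{i}" for i in range(n)]
    return CooccurrenceNetwork(nodes,
                               [(f"n{a}", f"n{b}", 1.0) for a, b in edges])


def brute_force_best_modularity(n, edges):
    """Best Newman-Girvan modularity over all set partitions (n ≤ 8)."""
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(edges)

    def partitions(elems):
        if not elems:
            yield []
            return
        first, rest = elems[0], elems[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1:]
            yield part + [[first]]

    best = -1.0
    for part in partitions(list(range(n))):
        q = nx.community.modularity(G, [set(b) for b in part])
        best = max(best, q)
    return best


class TestLouvain:
    def test_two_disjoint_triangles(self):
        net = _net_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        out = louvain(net)
        assert out.n_cliques == 2
        assert out.modularity == pytest.approx(0.5)
        assert sorted(set(out.membership.values())) == [1, 2]

    def test_complete_graph_single_clique(self):
        net = _net_from_edges(5, list(itertools.combinations(range(5), 2)))
        out = louvain(net)
        assert out.n_cliques == 1

    def test_isolated_nodes_are_singletons(self):
        net = _net_from_edges(4, [(0, 1)])
        out = louvain(net)
        assert out.membership["n2"] != out.membership["n3"]
        assert out.n_cliques == 3

    def test_modularity_matches_networkx_recomputation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(5, 12))
            edges = [(a, b) for a, b in itertools.combinations(range(n), 2)
                     if rng.random() < 0.4]
            net = _net_from_edges(n, edges)
            out = louvain(net)
            G = nx.Graph()
            G.add_nodes_from(net.nodes)
            G.add_edges_from([(a, b) for a, b, _ in net.edges])
            comms = {}
            for v, c in out.membership.items():
                comms.setdefault(c, set()).add(v)
            if G.number_of_edges() == 0:
                continue
            ref = nx.community.modularity(G, list(comms.values()))
            assert out.modularity == pytest.approx(ref, abs=1e-12)

    def test_never_exceeds_exhaustive_optimum(self):
        # the returned modularity is a real partition's modularity, so it can
        # never beat the brute-force best over all set partitions
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            edges = [(a, b) for a, b in itertools.combinations(range(n), 2)
                     if rng.random() < 0.5]
            if not edges:
                continue
            out = louvain(_net_from_edges(n, edges))
            best = brute_force_best_modularity(n, edges)
            assert out.modularity <= best + 1e-9

    def test_deterministic_default_sweep(self):
        rng = np.random.default_rng(3)
        edges = [(a, b) for a, b in itertools.combinations(range(10), 2)
                 if rng.random() < 0.3]
        net = _net_from_edges(10, edges)
        a, b = louvain(net), louvain(net)
        assert a.membership == b.membership and a.modularity == b.modularity

    def test_membership_is_partition_with_contiguous_ids(self):
        rng = np.random.default_rng(4)
        edges = [(a, b) for a, b in itertools.combinations(range(9), 2)
                 if rng.random() < 0.3]
        out = louvain(_net_from_edges(9, edges))
        assert set(out.membership) == set(out.nodes)
        ids = sorted(set(out.membership.values()))
        assert ids == list(range(1, len(ids) + 1))


class TestNodeGeochem:
    def test_profile_equal_to_ph_ranks(self):
        pH = np.array([2.0, 4.0, 6.0, 8.0, 9.0])
        t = _table([np.argsort(np.argsort(pH)) + 1.0,
                    [5, 4, 3, 2, 1]], normalized=True)
        g = GeochemTable(pd.DataFrame({"pH": pH},
                                      index=t.sample_ids), {"pH": ""})
        nodes, _ = node_geochem_correlation(t, g, ["pH"])
        assert nodes.at["A0", "pH"] == pytest.approx(1.0)
        assert nodes.at["A1", "pH"] == pytest.approx(-1.0)

    def test_rho_bounded(self, study):
        ds, _ = study
        filtered = filter_asvs(ds.counts)
        nodes, _ = node_geochem_correlation(filtered, ds.geochem,
                                            ["pH", "temperature"])
        vals = nodes.to_numpy()
        ok = ~np.isnan(vals)
        assert (vals[ok] >= -1 - 1e-12).all() and (vals[ok] <= 1 + 1e-12).all()

    def test_phototroph_cliques_track_ph(self, study):
        ds, truth = study
        filtered = filter_asvs(ds.counts)
        net = louvain(build_network(filtered))
        nodes, cliques = node_geochem_correlation(filtered, ds.geochem,
                                                  ["pH"], net)
        mem = pd.Series(net.membership)
        photo_cliques = []
        for c, members in mem.groupby(mem):
            if (truth.guilds.loc[members.index] == "phototroph").mean() > 0.5:
                photo_cliques.append(c)
        assert photo_cliques, "synthetic study should yield phototroph cliques"
        assert cliques.loc[photo_cliques, "pH"].median() > 0


def test_partition_modularity_agrees_with_networkx():
    rng = np.random.default_rng(5)
    edges = [(a, b) for a, b in itertools.combinations(range(8), 2)
             if rng.random() < 0.4]
    net = _net_from_edges(8, edges)
    membership = {v: (1 if i < 4 else 2) for i, v in enumerate(net.nodes)}
    G = nx.Graph()
    G.add_nodes_from(net.nodes)
    G.add_edges_from([(a, b) for a, b, _ in net.edges])
    ref = nx.community.modularity(G, [set(net.nodes[:4]), set(net.nodes[4:])])
    assert partition_modularity(net.adjacency(), membership) == pytest.approx(ref)
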