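"""Proximity scoring: distances, GO similarity, degree-matched nulls."""

import collections

import networkx as nx
import numpy as np
import pytest

from scdrugnet.proximity import (
    GOIndex,
    NetworkDistances,
    closest_distance,
    degree_bins,
    go_bp_similarity,
    null_distribution,
    sample_degree_matched,
    score_drug,
)


def bfs_closest_oracle(g, S, T):
    """Brute-force double loop: BFS from every s, min over T, mean over S'."""
    mins = []
    for s in S:
        dist = {s: 0}
        queue = collections.deque([s])
        while queue:
            u = queue.popleft()
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        reach = [dist[t] for t in T if t in dist]
        if reach:
            mins.append(min(reach))
    return sum(mins) / len(mins) if mins else None


def test_closest_distance_basic_cases():
    g = nx.path_graph(["a", "b", "c", "d"])
    assert closest_distance({"a", "d"}, {"b"}, g) == pytest.approx(1.5)
    assert closest_distance({"b"}, {"a", "b"}, g) == pytest.approx(0.0)
    g.add_edge("p", "q")  # disconnected component
    assert closest_distance({"p"}, {"a"}, g) is None


def test_closest_distance_matches_bfs_oracle_on_random_graphs():
    rng = np.random.default_rng(9)
    for _ in range(15):
        g = nx.gnp_random_graph(60, 0.06, seed=int(rng.integers(1 << 30)))
        nodes = list(g.nodes)
        S = set(rng.choice(nodes, size=6, replace=False))
        T = set(rng.choice(nodes, size=8, replace=False))
        got = closest_distance(S, T, g)
        expected = bfs_closest_oracle(g, S, T)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_go_similarity_hand_cases():
    ann = {"s": {"t1", "t2"}, "u": {"t2", "t3"}}
    assert go_bp_similarity({"s"}, {"s"}, ann) == pytest.approx(1.0)
    assert go_bp_similarity({"s"}, {"u"}, ann) == pytest.approx(1 / 3)
    disjoint = {"a": {"x"}, "b": {"y"}}
    assert go_bp_similarity({"a"}, {"b"}, disjoint) == pytest.approx(0.0)
    assert go_bp_similarity({"a"}, {"unannotated"}, disjoint) == 0.0


def test_goindex_matches_set_implementation():
    rng = np.random.default_rng(5)
    g = nx.gnp_random_graph(40, 0.1, seed=1)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    vocab = [f"T{i}" for i in range(20)]
    ann = {
        n: set(rng.choice(vocab, size=rng.integers(0, 6), replace=False))
        for n in g.nodes
    }
    nd = NetworkDistances(g)
    go = GOIndex(nd, ann)
    for _ in range(20):
        S = set(rng.choice(nd.nodes, size=5, replace=False))
        T = set(rng.choice(nd.nodes, size=7, replace=False))
        fast = go.bma_similarity(nd.to_indices(S), nd.to_indices(T))
        slow = go_bp_similarity(S, T, ann)
        assert fast == pytest.approx(slow, abs=1e-12)


def er_network(n=120, p=0.05, seed=2):
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    g.graph["cell_type"] = "TOY"
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def test_degree_matched_sampling_preserves_bin_profile():
    g = er_network()
    nd = NetworkDistances(g)
    bins = degree_bins(nd)
    rng = np.random.default_rng(0)
    module = nd.to_indices(set(np.array(nd.nodes)[:15]))
    samples = sample_degree_matched(nd, module, 50, rng)
    want = sorted(bins[module])
    for row in samples:
        assert sorted(bins[row]) == want
        assert len(set(row)) == len(row)  # without replacement within a draw


def test_null_distribution_deterministic_under_seed():
    g = er_network()
    nd = NetworkDistances(g)
    ann = {n: {f"T{int(n[1:]) % 7}"} for n in nd.nodes}
    module = set(nd.nodes[:12])
    disease = set(nd.nodes[40:60])
    d1, s1 = null_distribution(nd, module, disease, ann, n_perm=200, seed=3)
    d2, s2 = null_distribution(nd, module, disease, ann, n_perm=200, seed=3)
    assert np.array_equal(d1, d2) and np.array_equal(s1, s2)


def test_null_mean_matches_uniform_resampling_oracle():
    """Degree-aware null mean of the closest distance agrees with an
    independent resampling oracle on a degree-homogeneous random graph."""
    g = er_network(200, 0.05, seed=7)
    nd = NetworkDistances(g)
    rng = np.random.default_rng(11)
    disease = set(rng.choice(nd.nodes, size=20, replace=False))
    module = set(rng.choice(sorted(set(nd.nodes) - disease), size=10, replace=False))
    ann = {n: {"T0"} for n in nd.nodes}
    d_null, _ = null_distribution(nd, module, disease, ann, n_perm=2000, seed=1)
    # oracle: plain resampling of 10-node sets with python-loop BFS distances
    oracle_vals = []
    for _ in range(500):
        S = rng.choice(nd.nodes, size=10, replace=False)
        oracle_vals.append(bfs_closest_oracle(g, S, disease))
    se = np.std(oracle_vals) / np.sqrt(len(oracle_vals)) + np.std(d_null) / np.sqrt(len(d_null))
    assert abs(np.mean(d_null) - np.mean(oracle_vals)) < 5 * se + 0.05


def test_addone_empirical_p_floor():
    g = er_network()
    nd = NetworkDistances(g)
    ann = {n: {f"T{int(n[1:]) % 5}"} for n in nd.nodes}
    disease = set(nd.nodes[:25])
    module = set(nd.nodes[:12])  # inside the disease set: best possible score
    res = score_drug(module, disease, nd, ann, n_perm=99, seed=0)
    assert res.empirical_p >= 1 / 100
    assert res.combined_z == pytest.approx(res.z_distance + res.z_dissimilarity)
    assert res.d_closest == pytest.approx(0.0)


def test_embedded_module_scores_strongly_negative():
    g = er_network(150, 0.06, seed=4)
    nd = NetworkDistances(g)
    rng = np.random.default_rng(2)
    ann = {
        n: set(rng.choice([f"T{i}" for i in range(10)], size=3, replace=False))
        for n in nd.nodes
    }
    disease = set(nd.nodes[:40])
    module = set(nd.nodes[5:20])
    res = score_drug(module, disease, nd, ann, n_perm=500, seed=0)
    assert res.combined_z < -2
    assert res.significant


def test_random_module_p_is_roughly_uniform():
    g = er_network(150, 0.06, seed=8)
    nd = NetworkDistances(g)
    rng = np.random.default_rng(6)
    ann = {
        n: set(rng.choice([f"T{i}" for i in range(10)], size=3, replace=False))
        for n in nd.nodes
    }
    disease = set(rng.choice(nd.nodes, size=30, replace=False))
    pvals = []
    for i in range(60):
        sample = sample_degree_matched(
            nd, nd.to_indices(rng.choice(nd.nodes, 12, replace=False)), 1, rng
        )[0]
        module = {nd.nodes[j] for j in sample}
        res = score_drug(module, disease, nd, ann, n_perm=200, seed=100 + i)
        pvals.append(res.empirical_p)
    assert 0.2 < np.mean(pvals) < 0.8  # no systematic shift
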