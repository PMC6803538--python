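"""Connectivity networks and nodal graph metrics vs enumeration oracles."""

import itertools
from collections import deque

import numpy as np
import pytest

from neurointent.network import (
    METRICS,
    betweenness,
    clustering_coefficient,
    connectivity,
    degree,
    eigenvector_centrality,
    feature_table,
    fisher_z,
    grand_average_networks,
    local_efficiency,
    nodal_features,
    proportional_threshold,
)

from conftest import random_adjacency


# --------------------------------------------------------------------------
# Brute-force oracles (pure enumeration, independent of the implementation)


def _bfs_dist(adj, src):
    n = len(adj)
    dist = [None] * n
    dist[src] = 0
    q = deque([src])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u][v] and dist[v] is None:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _count_shortest_paths(adj, s, t):
    """Number of shortest s-t paths by exhaustive BFS-layer DP."""
    dist = _bfs_dist(adj, s)
    if dist[t] is None:
        return 0, None
    counts = [0] * len(adj)
    counts[s] = 1
    order = sorted((d, v) for v, d in enumerate(dist) if d is not None)
    for d, v in order:
        if v == s:
            continue
        counts[v] = sum(
            counts[u] for u in range(len(adj)) if adj[u][v] and dist[u] == d - 1
        )
    return counts[t], dist[t]


def _betweenness_oracle(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        total = 0.0
        for s, t in itertools.combinations(
            [v for v in range(n) if v != i], 2
        ):
            sigma_st, d_st = _count_shortest_paths(adj, s, t)
            if sigma_st == 0:
                continue
            sigma_si, d_si = _count_shortest_paths(adj, s, i)
            sigma_it, d_it = _count_shortest_paths(adj, i, t)
            if d_si is not None and d_it is not None and d_si + d_it == d_st:
                total += sigma_si * sigma_it / sigma_st
        out[i] = total / ((n - 1) * (n - 2) / 2)
    return out


def _clustering_oracle(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [v for v in range(n) if adj[i][v]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(adj[u][v] for u, v in itertools.combinations(nbrs, 2))
        out[i] = 2 * tri / (k * (k - 1))
    return out


def _global_efficiency_oracle(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    acc = 0.0
    for s, t in itertools.permutations(range(n), 2):
        d = _bfs_dist(adj, s)[t]
        acc += 0.0 if d is None else 1.0 / d
    return acc / (n * (n - 1))


def _local_efficiency_oracle(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [v for v in range(n) if adj[i][v]]
        if len(nbrs) < 2:
            continue
        sub = [[adj[u][v] for v in nbrs] for u in nbrs]
        out[i] = _global_efficiency_oracle(sub)
    return out


def _eigenvector_oracle(adj):
    """Power iteration on the largest connected component.

    Iterates on A + n*I (same Perron vector) so bipartite components, whose
    extreme adjacency eigenvalues have equal magnitude, still converge.
    """
    n = len(adj)
    comp = _largest_component(adj)
    out = np.zeros(n)
    if len(comp) < 2:
        return out
    a = np.asarray(adj, dtype=float)[np.ix_(comp, comp)]
    a = a + len(comp) * np.eye(len(comp))
    v = np.ones(len(comp)) / np.sqrt(len(comp))
    for _ in range(100_000):
        w = a @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < 1e-14:
            v = w
            break
        v = w
    out[comp] = np.abs(v)
    return out


def _largest_component(adj):
    n = len(adj)
    seen, best = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp = [v for v, d in enumerate(_bfs_dist(adj, s)) if d is not None]
        seen.update(comp)
        if len(comp) > len(best):
            best = comp
    return sorted(best)


ORACLES = {
    "degree": lambda a: np.asarray(a, dtype=float).sum(axis=1),
    "clustering": _clustering_oracle,
    "betweenness": _betweenness_oracle,
    "eigenvector": _eigenvector_oracle,
    "local_efficiency": _local_efficiency_oracle,
}
IMPLS = {
    "degree": degree,
    "clustering": clustering_coefficient,
    "betweenness": betweenness,
    "eigenvector": eigenvector_centrality,
    "local_efficiency": local_efficiency,
}


# --------------------------------------------------------------------------
# Closed-form cases

TRIANGLE = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=bool)
PATH3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
STAR4 = np.zeros((4, 4), dtype=bool)
STAR4[0, 1:] = STAR4[1:, 0] = True
K4 = ~np.eye(4, dtype=bool)


class TestClosedFormMetrics:
    def test_degree(self):
        assert np.array_equal(degree(TRIANGLE), [2, 2, 2])
        assert np.array_equal(degree(PATH3), [1, 2, 1])

    def test_clustering(self):
        assert np.array_equal(clustering_coefficient(TRIANGLE), [1, 1, 1])
        assert clustering_coefficient(STAR4)[0] == 0.0
        assert np.array_equal(clustering_coefficient(K4), np.ones(4))

    def test_betweenness(self):
        assert betweenness(PATH3)[1] == pytest.approx(1.0)
        assert np.allclose(betweenness(K4), 0.0)

    def test_eigenvector(self):
        assert np.allclose(eigenvector_centrality(K4), 0.5)  # 1/sqrt(4)
        v = eigenvector_centrality(STAR4)
        assert v[0] / v[1] == pytest.approx(np.sqrt(3))  # closed-form ratio

    def test_local_efficiency(self):
        assert local_efficiency(TRIANGLE)[0] == pytest.approx(1.0)
        assert local_efficiency(STAR4)[0] == 0.0

    def test_empty_graph_all_zero(self):
        empty = np.zeros((5, 5), dtype=bool)
        feats = np.stack([IMPLS[m](empty) for m in METRICS], axis=1)
        assert np.allclose(feats, 0.0)

    def test_complete_graph_features(self):
        n = 5
        kn = ~np.eye(n, dtype=bool)
        assert np.array_equal(degree(kn), np.full(n, n - 1))
        assert np.allclose(clustering_coefficient(kn), 1.0)
        assert np.allclose(betweenness(kn), 0.0)


@pytest.mark.parametrize("metric", METRICS)
def test_metrics_match_enumeration_oracles(metric):
    rng = np.random.default_rng(0)
    for trial in range(40):
        n = int(rng.integers(3, 9))
        adj = random_adjacency(rng, n, p=float(rng.uniform(0.2, 0.8)))
        got = IMPLS[metric](adj)
        want = ORACLES[metric](adj.astype(int).tolist())
        assert np.allclose(got, want, atol=1e-8), f"{metric} trial {trial}"


def test_metrics_permutation_equivariant():
    rng = np.random.default_rng(1)
    adj = random_adjacency(rng, 8, 0.4)
    perm = rng.permutation(8)
    padj = adj[np.ix_(perm, perm)]
    for m in METRICS:
        assert np.allclose(IMPLS[m](adj)[perm], IMPLS[m](padj), atol=1e-10), m


class TestFisherZ:
    def test_closed_form_value(self):
        assert fisher_z(0.9) == pytest.approx(np.arctanh(0.9), abs=1e-12)
        assert fisher_z(0.9) == pytest.approx(1.4722, abs=1e-4)

    def test_clipped_at_unity(self):
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))
        assert np.isfinite(fisher_z(np.array([-1.0, 1.0]))).all()

    def test_odd_and_monotone(self):
        r = np.linspace(-0.99, 0.99, 41)
        z = fisher_z(r)
        assert np.allclose(z, -fisher_z(-r), atol=1e-12)
        assert np.all(np.diff(z) > 0)


class TestConnectivity:
    def test_duplicated_channel_clipped(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        net = connectivity(np.vstack([x, x, rng.standard_normal(100)]), 0.5)
        assert net.weights[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_constant_channel_zeroed_with_warning(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 50))
        data[1] = 4.2
        with pytest.warns(UserWarning, match="constant channel"):
            net = connectivity(data, 0.5)
        assert np.all(net.weights[1] == 0.0)

    def test_symmetry_zero_diagonal(self):
        data = np.random.default_rng(4).standard_normal((6, 80))
        net = connectivity(data, 0.3)
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
        assert np.array_equal(net.binary, net.binary.T)

    def test_independent_channels_mean_r_shrinks(self):
        rng = np.random.default_rng(5)
        r_means = []
        for t_len in (50, 5000):
            z = connectivity(rng.standard_normal((8, t_len)), 0.3).weights
            iu = np.triu_indices(8, 1)
            r_means.append(np.abs(np.tanh(z[iu])).mean())
        assert r_means[1] < r_means[0] / 3

    def test_proportional_threshold_density_and_ties(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0  # tie with (0,1)
        w[0, 2] = w[2, 0] = 0.5
        adj = proportional_threshold(w, 1 / 6)  # keep exactly one edge
        assert adj.sum() == 2  # one undirected edge
        assert adj[0, 1]  # lexicographically first among tied pairs

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            connectivity(np.zeros((3, 2)), 0.3)


class TestFeatureTable:
    def test_columns_and_shape(self, toy_epochs):
        table = feature_table(toy_epochs, window_s=(0.0, 1.0), density=0.4)
        assert table.values.shape == (12, 4 * 5)
        assert table.columns[0] == "EEG:ch1:degree"
        assert table.columns[4] == "EEG:ch1:local_efficiency"
        assert not np.isnan(table.values).any()

    def test_rows_match_per_trial_nodal_features(self, toy_epochs):
        table = feature_table(toy_epochs, window_s=(0.0, 1.0), density=0.4)
        mask = toy_epochs.time_mask(0.0, 1.0)
        net = connectivity(toy_epochs.data[3][:, mask], 0.4)
        assert np.allclose(table.values[3], nodal_features(net).reshape(-1))

    def test_grand_average_networks_keyed_by_condition(self, toy_epochs):
        nets = grand_average_networks(toy_epochs, (0.0, 1.0), 0.3)
        assert set(nets) == {"Sd", "Sm", "Su"}
        for net in nets.values():
            assert net.weights.shape == (4, 4)


def test_within_condition_networks_more_similar_than_between(small_eeg_epochs):
    """Condition-specific covariance: mean within-condition edge correlation
    exceeds between-condition (Sd vs the rest; Sm and Su share EEG blocks)."""
    ep = small_eeg_epochs
    mask = ep.time_mask(0.0, 3.5)
    iu = np.triu_indices(ep.n_channels, 1)
    vecs, labs = [], []
    for i in range(ep.n_trials):
        net = connectivity(ep.data[i][:, mask], 0.3)
        vecs.append(net.weights[iu])
        labs.append(ep.labels[i])
    vecs = np.asarray(vecs)
    labs = np.asarray(labs)
    c = np.corrcoef(vecs)
    within, between = [], []
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            # Sm and Su share the planted EEG partition by design
            same = labs[i] == labs[j] or {labs[i], labs[j]} == {"Sm", "Su"}
            (within if same else between).append(c[i, j])
    assert np.mean(within) > np.mean(between)
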