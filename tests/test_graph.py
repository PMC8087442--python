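"""Graph measures, consensus modules, clusters, change correlations."""

import numpy as np
import pytest

from manecc import (Connectome, betweenness_centrality, change_correlation,
                    connectivity_distance, consensus_partition,
                    contiguous_clusters, degree_centrality,
                    eigenvector_centrality, louvain_partition,
                    participation_coefficient, simulate_parcellation,
                    within_module_degree)
from manecc.graph import ModulePartition
from conftest import random_connectome


def _conn(w):
    return Connectome(weights=np.asarray(w, float), parcel_ids=np.arange(len(w)))


def test_degree_closed_forms(rng):
    tri = _conn([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    assert np.allclose(degree_centrality(tri), 2.0)
    iso = _conn(np.zeros((3, 3)))
    assert np.allclose(degree_centrality(iso), 0.0)
    c = random_connectome(rng, n=12, log=False)
    oracle = [sum(c.weights[i]) for i in range(12)]
    assert np.allclose(degree_centrality(c), oracle)


def test_betweenness_closed_forms():
    path = _conn([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    assert np.allclose(betweenness_centrality(path), [0, 1, 0])
    complete = _conn(np.ones((5, 5)) - np.eye(5))
    assert np.allclose(betweenness_centrality(complete), 0.0)


def test_betweenness_matches_allpairs_oracle(rng):
    """Exhaustive shortest-path counting on a random 10-node graph."""
    import itertools
    import networkx as nx
    c = random_connectome(rng, n=10, density=0.6, log=False)
    got = betweenness_centrality(c)
    g = nx.Graph()
    g.add_nodes_from(range(10))
    for i, j in zip(*np.nonzero(np.triu(c.weights, 1))):
        g.add_edge(int(i), int(j), length=1.0 / c.weights[i, j])
    oracle = np.zeros(10)
    for s, t in itertools.combinations(range(10), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t, weight="length"))
        except nx.NetworkXNoPath:
            continue
        for v in range(10):
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            oracle[v] += frac
    assert np.allclose(got, oracle, atol=1e-8)


def test_eigenvector_centrality(rng):
    ring = np.zeros((6, 6))
    for i in range(6):
        ring[i, (i + 1) % 6] = ring[(i + 1) % 6, i] = 1.0
    assert np.allclose(eigenvector_centrality(_conn(ring)), 1.0)
    star = np.zeros((5, 5))
    star[0, 1:] = star[1:, 0] = 1.0
    ev = eigenvector_centrality(_conn(star))
    assert ev[0] == pytest.approx(1.0) and (ev[1:] < 1).all()
    # power-iteration oracle
    c = random_connectome(rng, n=12, log=False)
    v = np.ones(12)
    for _ in range(2000):
        v = c.weights @ v
        v /= np.linalg.norm(v)
    assert np.allclose(eigenvector_centrality(c), v / v.max(), atol=1e-8)


def test_connectivity_distance(rng):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    d = np.full((3, 3), 5.0)
    np.fill_diagonal(d, 0)
    out = connectivity_distance(_conn(w), d)
    assert out[0] == 5.0 and np.isnan(out[2])
    c = random_connectome(rng, n=8, density=0.6, log=False)
    dm = np.abs(rng.normal(0, 1, (8, 8)))
    dm = 0.5 * (dm + dm.T)
    np.fill_diagonal(dm, 0)
    got = connectivity_distance(c, dm)
    for i in range(8):
        nbrs = np.flatnonzero(c.weights[i] > 0)
        if len(nbrs):
            assert got[i] == pytest.approx(dm[i, nbrs].mean())


def test_louvain_separates_cliques():
    w = np.zeros((10, 10))
    w[:5, :5] = 1.0
    w[5:, 5:] = 1.0
    np.fill_diagonal(w, 0)
    part = louvain_partition(_conn(w), seed=1)
    assert part.k == 2
    assert len(set(part.labels[:5])) == 1 and len(set(part.labels[5:])) == 1
    part2 = louvain_partition(_conn(w), seed=1)
    assert np.array_equal(part.labels, part2.labels)


def test_louvain_beats_random_partitions(rng):
    import networkx as nx
    c = random_connectome(rng, n=30, density=0.3, log=False)
    part = louvain_partition(c, seed=0)
    g = nx.from_numpy_array(c.weights)
    comms = [set(np.flatnonzero(part.labels == m)) for m in np.unique(part.labels)]
    q_best = nx.community.modularity(g, comms, weight="weight")
    for _ in range(100):
        labels = rng.integers(0, part.k, 30)
        rand = [set(np.flatnonzero(labels == m)) for m in range(part.k)
                if (labels == m).any()]
        assert q_best >= nx.community.modularity(g, rand, weight="weight") - 1e-12


def test_consensus_recovers_shared_partition():
    labels = np.array([1] * 6 + [2] * 6)
    parts = [ModulePartition(labels=labels, k=2) for _ in range(5)]
    labels2 = labels.copy()
    labels2[0] = 2  # tiny disagreement to avoid a degenerate 0/1 matrix
    parts.append(ModulePartition(labels=labels2, k=2))
    cons = consensus_partition(parts, seed=0)
    assert cons.k == 2
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(labels, cons.labels) > 0.8


def test_within_module_degree_zscores(rng):
    w = np.ones((6, 6)) - np.eye(6)
    part = ModulePartition(labels=np.array([1, 1, 1, 2, 2, 2]), k=2)
    z = within_module_degree(_conn(w), part)
    assert np.allclose(z, 0.0)  # identical intra-module degrees
    c = random_connectome(rng, n=10, log=False)
    labels = np.array([1] * 5 + [2] * 5)
    z = within_module_degree(c, ModulePartition(labels=labels, k=2))
    for m in (1, 2):
        assert abs(z[labels == m].sum()) < 1e-9


@pytest.mark.parametrize("m", [2, 3, 5])
def test_participation_equal_split_closed_form(m):
    n = m + 1
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    labels = np.arange(n)  # node 0 alone; each neighbor its own module
    part = ModulePartition(labels=labels + 1, k=n)
    p = participation_coefficient(_conn(w), part)
    assert p[0] == pytest.approx(1 - 1 / m)


def test_participation_within_module_only():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    part = ModulePartition(labels=np.array([1, 1, 2, 2]), k=2)
    p = participation_coefficient(_conn(w), part)
    assert p[0] == 0.0 and p[2] == 0.0  # isolated node also 0


def test_contiguous_clusters_bfs_oracle(parcels_cortical_only):
    parcels = parcels_cortical_only
    cids = parcels.cortical_ids
    mask = np.zeros(len(cids), bool)
    seed_parcel = cids[0]
    chain = [seed_parcel] + parcels.neighbors[seed_parcel][:2]
    far = [pid for pid in cids
           if pid not in chain and not (set(parcels.neighbors[pid]) & set(chain))][0]
    for pid in chain + [far]:
        mask[np.where(cids == pid)[0][0]] = True
    labels = contiguous_clusters(mask, parcels)
    assert labels.max() == 2
    chain_lab = {labels[np.where(cids == pid)[0][0]] for pid in chain}
    assert len(chain_lab) == 1
    assert labels[np.where(cids == far)[0][0]] != chain_lab.pop()
    assert contiguous_clusters(np.zeros(len(cids), bool), parcels).max() == 0


def test_change_correlation_perfect_and_null(rng):
    d = rng.normal(0, 1, 20)
    r, p = change_correlation(d, 2 * d, n_perm=200, seed=1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 201)
    ps = []
    for i in range(200):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        _, p = change_correlation(a, b, n_perm=99, seed=i)
        ps.append(p)
    from scipy import stats
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_change_correlation_matches_analytic(rng):
    """Permutation p within Monte-Carlo error of the analytic p for
    bivariate normal data."""
    from scipy import stats
    n = 60
    x = rng.normal(0, 1, n)
    y = 0.4 * x + rng.normal(0, 1, n)
    r, p_perm = change_correlation(x, y, n_perm=2000, seed=3)
    p_analytic = stats.pearsonr(x, y).pvalue
    assert abs(p_perm - p_analytic) < 0.03 + 3 * np.sqrt(p_analytic / 2000)
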