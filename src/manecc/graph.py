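"""Graph-theoretical context for manifold findings.

Nodal centralities (degree, betweenness, eigenvector), connectivity distance,
Louvain community detection with a k-means consensus across subjects, modular
measures (within-module degree z-score, participation coefficient), spatially
contiguous clusters of significant parcels, and permutation-tested
change-change correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datatypes import Connectome
from .parcellation import ParcelTable


def _graph(conn: Connectome, length: bool = False) -> nx.Graph:
    g = nx.Graph()
    w = conn.weights
    n = w.shape[0]
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(w, k=1))
    for i, j in zip(iu, ju):
        attrs = {"weight": w[i, j]}
        if length:
            attrs["length"] = 1.0 / w[i, j]  # strong edges are short
        g.add_edge(int(i), int(j), **attrs)
    return g


def degree_centrality(conn: Connectome) -> np.ndarray:
    """Row-wise sum of the weighted connectivity matrix."""
    return conn.weights.sum(axis=1)


def betweenness_centrality(conn: Connectome) -> np.ndarray:
    """Weighted shortest-path betweenness (edge length = 1/weight)."""
    g = _graph(conn, length=True)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(conn.n_parcels)])


def eigenvector_centrality(conn: Connectome) -> np.ndarray:
    """Principal-eigenvector loading, unit maximum, computed per component."""
    w = conn.weights
    n = w.shape[0]
    from scipy.sparse.csgraph import connected_components
    n_comp, labels = connected_components((w > 0).astype(np.int8), directed=False)
    if n_comp > 1:
        warnings.warn(f"graph has {n_comp} components; "
                      "eigenvector centrality computed per component")
    out = np.zeros(n)
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            continue
        sub = w[np.ix_(idx, idx)]
        evals, evecs = np.linalg.eigh(sub)
        v = np.abs(evecs[:, -1])  # Perron vector is nonnegative
        out[idx] = v
    if out.max() > 0:
        out = out / out.max()
    return out


def connectivity_distance(conn: Connectome, distances: np.ndarray) -> np.ndarray:
    """Mean spatial distance to structurally connected nodes (NaN if isolated)."""
    d = np.asarray(distances, float)
    if d.shape != conn.weights.shape:
        raise ValueError("distance matrix must match connectome size")
    if (d < 0).any() or np.abs(d - d.T).max() > 1e-9:
        raise ValueError("distances must be symmetric and nonnegative")
    support = conn.weights > 0
    np.fill_diagonal(support, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.where(support.any(axis=1),
                       (d * support).sum(axis=1) / support.sum(axis=1), np.nan)
    return out


@dataclass
class ModulePartition:
    labels: np.ndarray  # contiguous 1..k
    k: int
    gamma: float = 1.0
    silhouette: float = np.nan
    method: str = "louvain"


def louvain_partition(conn: Connectome, gamma: float = 1.0, seed: int = 0,
                      n_restarts: int = 10) -> ModulePartition:
    """Best-modularity Louvain partition over seeded restarts."""
    if conn.weights.sum() == 0:
        raise ValueError("empty graph")
    g = _graph(conn)
    best, best_q = None, -np.inf
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma, seed=seed * 10007 + r)
        q = nx.community.modularity(g, comms, weight="weight", resolution=gamma)
        if q > best_q:
            best, best_q = comms, q
    labels = np.zeros(conn.n_parcels, dtype=int)
    # stable module numbering: order communities by their smallest node
    for k, comm in enumerate(sorted(best, key=min), start=1):
        labels[list(comm)] = k
    return ModulePartition(labels=labels, k=len(best), gamma=gamma)


def consensus_partition(partitions: list[ModulePartition], k_range=range(2, 11),
                        seed: int = 0, n_init: int = 50) -> ModulePartition:
    """K-means consensus over subject partitions.

    Per-subject binary co-assignment matrices are averaged; rows of the group
    matrix are clustered for each candidate k and the k maximizing the mean
    silhouette is kept.
    """
    if len(partitions) < 2:
        raise ValueError("need >= 2 partitions")
    n = len(partitions[0].labels)
    co = np.zeros((n, n))
    for p in partitions:
        lab = np.asarray(p.labels)
        co += lab[:, None] == lab[None, :]
    co /= len(partitions)
    if np.allclose(co, co[0]):
        raise ValueError("degenerate co-assignment matrix (identical rows)")
    best = (None, -np.inf, None)
    for k in k_range:
        if k >= n:
            break
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(co)
        lab = km.labels_
        if len(np.unique(lab)) < 2:
            continue
        sil = silhouette_score(co, lab, metric="euclidean")
        if sil > best[1]:
            best = (k, sil, lab)
    k, sil, lab = best
    labels = np.zeros(n, dtype=int)
    for new, old in enumerate(sorted(np.unique(lab), key=lambda c: np.flatnonzero(lab == c)[0]), 1):
        labels[lab == old] = new
    return ModulePartition(labels=labels, k=k, silhouette=float(sil),
                           method="consensus")


def within_module_degree(conn: Connectome, partition: ModulePartition) -> np.ndarray:
    """Intra-module strength, z-scored within each module (size-1 modules: 0)."""
    w = conn.weights
    labels = np.asarray(partition.labels)
    z = np.zeros(conn.n_parcels)
    for mod in np.unique(labels):
        idx = np.flatnonzero(labels == mod)
        if len(idx) < 2:
            continue
        strength = w[np.ix_(idx, idx)].sum(axis=1)
        sd = strength.std(ddof=0)
        if sd > 0:
            z[idx] = (strength - strength.mean()) / sd
    return z


def participation_coefficient(conn: Connectome, partition: ModulePartition) -> np.ndarray:
    """P_i = 1 - sum_s (kappa_is / k_i)^2; isolated nodes get 0."""
    w = conn.weights
    labels = np.asarray(partition.labels)
    k = w.sum(axis=1)
    p = np.zeros(conn.n_parcels)
    nz = k > 0
    acc = np.zeros(conn.n_parcels)
    for mod in np.unique(labels):
        kappa = w[:, labels == mod].sum(axis=1)
        acc[nz] += (kappa[nz] / k[nz])**2
    p[nz] = 1.0 - acc[nz]
    return p


def contiguous_clusters(significance_mask: np.ndarray,
                        parcels: ParcelTable) -> np.ndarray:
    """Connected components of significant parcels on the adjacency graph.

    Returns per-cortical-parcel labels: 0 for non-significant, then 1..k with
    clusters ordered by size (descending, ties by smallest member id).
    """
    mask = np.asarray(significance_mask, bool)
    cids = parcels.cortical_ids
    if len(mask) != len(cids):
        raise ValueError("mask must cover all cortical parcels")
    pos = {pid: i for i, pid in enumerate(cids)}
    sig = set(cids[mask])
    comps = []
    seen: set[int] = set()
    for pid in cids[mask]:
        if pid in seen:
            continue
        stack, comp = [pid], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(u for u in parcels.neighbors.get(v, []) if u in sig and u not in seen)
        comps.append(sorted(comp))
    comps.sort(key=lambda c: (-len(c), c[0]))
    labels = np.zeros(len(cids), dtype=int)
    for k, comp in enumerate(comps, start=1):
        for pid in comp:
            labels[pos[pid]] = k
    return labels


def change_correlation(delta_feature: np.ndarray, delta_metric: np.ndarray,
                       n_perm: int = 1000, seed: int = 0):
    """Pearson r between per-subject changes, with a permutation p-value.

    The metric vector is shuffled across subjects; p is two-sided,
    (1 + #{|null r| >= |r|}) / (n_perm + 1).  Returns (r, p) or (nan, nan)
    when either vector has zero variance.
    """
    a = np.asarray(delta_feature, float)
    b = np.asarray(delta_metric, float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need aligned vectors with n >= 5")
    if a.std() == 0 or b.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    count = 0
    for _ in range(n_perm):
        null_r = az @ rng.permutation(bz) / len(a)
        if abs(null_r) >= abs(r) - 1e-15:
            count += 1
    return r, (1 + count) / (n_perm + 1)


def cluster_change_correlations(delta_ecc_by_cluster: dict[int, np.ndarray],
                                delta_metrics: dict[str, dict[int, np.ndarray]],
                                n_perm: int = 1000, seed: int = 0):
    """Batch change-change correlations with BH correction across clusters."""
    import pandas as pd
    from .lme import fdr_correct
    rows = []
    for metric, per_cluster in delta_metrics.items():
        for cl, dm in per_cluster.items():
            r, p = change_correlation(delta_ecc_by_cluster[cl], dm,
                                      n_perm=n_perm, seed=seed)
            rows.append(dict(metric=metric, cluster=cl, r=r, p=p))
    df = pd.DataFrame(rows)
    for metric in df.metric.unique():
        sel = df.metric == metric
        q, mask = fdr_correct(df.loc[sel, "p"].to_numpy())
        df.loc[sel, "q"] = q
        df.loc[sel, "significant"] = mask
    return df
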