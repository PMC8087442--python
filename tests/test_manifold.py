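"""Manifold core: affinity kernel, embeddings, alignment, eccentricity."""

import numpy as np
import pytest

from manecc import (AffinityMatrix, Connectome, Manifold, alignment_quality,
                    diffusion_map_embed, explained_variance,
                    manifold_eccentricity, normalized_angle_affinity,
                    pca_embed, procrustes_align, subcortical_weighted_manifold,
                    template_center)
from manecc.manifold import EccentricityMap, TemplateCenter, flag_poor_alignment
from conftest import random_connectome


# ---------------------------------------------------------------- affinity

def test_affinity_closed_forms():
    w = np.array([
        [0.0, 0.0, 1.0, 1.0],
        [0.0, 0.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 0.0],
        [1.0, 1.0, 0.0, 0.0],
    ])
    conn = Connectome(weights=w, parcel_ids=np.arange(4), log_transformed=True)
    aff = normalized_angle_affinity(conn, row_sparsity=0.0)
    assert aff.values[0, 1] == pytest.approx(1.0)   # identical rows
    assert aff.values[0, 2] == pytest.approx(0.5)   # orthogonal rows
    assert np.allclose(np.diag(aff.values), 1.0)
    assert aff.values.min() >= 0 and aff.values.max() <= 1


def test_affinity_antiparallel_rows_map_to_zero():
    rows = np.array([[1.0, -1.0], [-1.0, 1.0]])
    cos = np.clip(rows @ rows.T / 2.0, -1, 1)
    aff = 1 - np.arccos(cos) / np.pi
    assert aff[0, 1] == pytest.approx(0.0)


def test_affinity_rejects_dead_rows():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    conn = Connectome(weights=w, parcel_ids=np.arange(3), log_transformed=True)
    with pytest.raises(ValueError, match="parcel"):
        normalized_angle_affinity(conn, row_sparsity=0.0)


def test_affinity_scale_invariance(rng):
    conn = random_connectome(rng, n=15)
    a1 = normalized_angle_affinity(conn, row_sparsity=0.0).values
    conn2 = Connectome(conn.weights * 7.3, conn.parcel_ids, True)
    a2 = normalized_angle_affinity(conn2, row_sparsity=0.0).values
    assert np.allclose(a1, a2, atol=1e-12)


# ------------------------------------------------------------- diffusion map

def test_ring_graph_degenerate_pair_traces_circle():
    n = 12
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1.0
    np.fill_diagonal(a, 1.0)
    m = diffusion_map_embed(AffinityMatrix(values=a), alpha=0.5, t=0, k=2)
    assert m.eigenvalues[0] == pytest.approx(m.eigenvalues[1], abs=1e-10)
    radii = np.linalg.norm(m.coords, axis=1)
    assert np.allclose(radii, radii[0], rtol=1e-8)


def test_embedding_scale_invariance(rng):
    conn = random_connectome(rng, n=20)
    m1 = diffusion_map_embed(normalized_angle_affinity(conn, 0.0), k=3)
    conn2 = Connectome(conn.weights * 3.7, conn.parcel_ids, True)
    m2 = diffusion_map_embed(normalized_angle_affinity(conn2, 0.0), k=3)
    assert np.allclose(m1.coords, m2.coords, atol=1e-9)


def test_k_too_large_rejected(rng):
    conn = random_connectome(rng, n=6)
    aff = normalized_angle_affinity(conn, 0.0)
    with pytest.raises(ValueError, match="k="):
        diffusion_map_embed(aff, k=6)


def test_disconnected_affinity_rejected():
    a = np.eye(4)
    a[0, 1] = a[1, 0] = 0.5
    a[2, 3] = a[3, 2] = 0.5
    with pytest.raises(ValueError, match="disconnected"):
        diffusion_map_embed(AffinityMatrix(values=a), k=1)


# --------------------------------------------------------------------- PCA

def test_pca_matches_covariance_oracle(rng):
    conn = random_connectome(rng, n=10)
    m = pca_embed(conn, k=3)
    x = conn.weights - conn.weights.mean(axis=0)
    evals, evecs = np.linalg.eigh(x.T @ x)
    idx = np.argsort(evals)[::-1][:3]
    for j in range(3):
        proj = x @ evecs[:, idx[j]]
        r = np.corrcoef(m.coords[:, j], proj)[0, 1]
        assert abs(abs(r) - 1) < 1e-10
        assert np.linalg.norm(m.coords[:, j]) == pytest.approx(np.linalg.norm(proj))


def test_pca_rank_one_matrix():
    v = np.arange(1.0, 7.0)
    x = np.outer(v, v)  # rank-1 profile matrix (centering preserves rank 1)
    conn = Connectome(weights=x, parcel_ids=np.arange(6), log_transformed=True)
    m = pca_embed(conn, k=1)
    assert m.variance_explained[0] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="rank"):
        pca_embed(Connectome(np.zeros((4, 4)), np.arange(4), True), k=2)


# --------------------------------------------------------------- Procrustes

def test_procrustes_identity_and_rotation_recovery(rng):
    coords = rng.normal(0, 1, (30, 3))
    tpl = Manifold(coords=coords, eigenvalues=np.ones(3))
    same = procrustes_align(tpl, tpl)
    assert np.allclose(same.coords, coords, atol=1e-12)
    q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
    rotated = Manifold(coords=coords @ q, eigenvalues=np.ones(3))
    back = procrustes_align(rotated, tpl)
    assert np.allclose(back.coords, coords, atol=1e-9)
    assert back.aligned_to == "template"


def test_procrustes_matches_svd_oracle(rng):
    src = Manifold(coords=rng.normal(0, 1, (8, 3)), eigenvalues=np.ones(3))
    tpl = Manifold(coords=rng.normal(0, 1, (8, 3)), eigenvalues=np.ones(3))
    aligned = procrustes_align(src, tpl)
    u, _, vt = np.linalg.svd(src.coords.T @ tpl.coords)
    r_oracle = u @ vt
    assert np.allclose(aligned.coords, src.coords @ r_oracle, atol=1e-10)


def test_procrustes_preserves_pairwise_distances(rng):
    src = Manifold(coords=rng.normal(0, 1, (12, 3)), eigenvalues=np.ones(3))
    tpl = Manifold(coords=rng.normal(0, 1, (12, 3)), eigenvalues=np.ones(3))
    aligned = procrustes_align(src, tpl)
    from scipy.spatial.distance import pdist
    assert np.allclose(pdist(src.coords), pdist(aligned.coords), atol=1e-10)


def test_alignment_improves_template_correlation(rng):
    """Randomly rotated/sign-flipped copies correlate better after alignment."""
    tpl = Manifold(coords=rng.normal(0, 1, (40, 3)), eigenvalues=np.ones(3))
    for _ in range(10):
        q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
        src = Manifold(coords=tpl.coords @ q + rng.normal(0, 0.1, (40, 3)),
                       eigenvalues=np.ones(3))
        before = np.nanmean(alignment_quality(src, tpl))
        after = np.nanmean(alignment_quality(procrustes_align(src, tpl), tpl))
        assert after > before


def test_alignment_quality_closed_forms(rng):
    tpl = Manifold(coords=rng.normal(0, 1, (20, 3)), eigenvalues=np.ones(3))
    r = alignment_quality(tpl, tpl)
    assert np.allclose(r, 1.0)
    flipped = Manifold(coords=tpl.coords * np.array([-1, 1, 1]),
                       eigenvalues=np.ones(3))
    assert alignment_quality(flipped, tpl)[0] == pytest.approx(-1.0)
    quals = [np.array([0.9 - 0.01 * i]) for i in range(20)]
    assert sorted(flag_poor_alignment(quals, 0.1).tolist()) == [18, 19]


# ------------------------------------------------------- eccentricity et al.

def test_template_center_is_column_mean(rng):
    coords = rng.normal(0, 1, (50, 3))
    tpl = Manifold(coords=coords, eigenvalues=np.ones(3))
    c = template_center(tpl)
    oracle = np.array([sum(coords[:, j]) / 50 for j in range(3)])
    assert np.allclose(c.center, oracle, atol=1e-12)
    two = Manifold(coords=np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
                   eigenvalues=np.ones(3))
    assert np.allclose(template_center(two).center, 0.0)


def test_eccentricity_identities():
    center = TemplateCenter(center=np.zeros(3))
    m = Manifold(coords=np.array([[3.0, 4.0, 0.0], [0.0, 0.0, 0.0]]),
                 eigenvalues=np.ones(3), aligned_to="t")
    ecc = manifold_eccentricity(m, center)
    assert ecc.values[0] == pytest.approx(5.0)
    assert ecc.values[1] == pytest.approx(0.0)


def test_eccentricity_requires_alignment():
    center = TemplateCenter(center=np.zeros(3))
    m = Manifold(coords=np.zeros((2, 3)), eigenvalues=np.ones(3))
    with pytest.raises(ValueError, match="aligned"):
        manifold_eccentricity(m, center)


def test_subcortical_projection_oracle(rng):
    man = Manifold(coords=rng.normal(0, 1, (10, 3)), eigenvalues=np.ones(3),
                   aligned_to="t")
    w = rng.uniform(0, 1, (4, 10))
    proj = subcortical_weighted_manifold(w, man)
    for s in range(4):
        acc = 0.0
        for e in range(3):
            acc += sum(w[s, j] / w[s].sum() * man.coords[j, e] for j in range(10))
        assert proj.values[s] == pytest.approx(acc / 3, abs=1e-12)
    one_hot = np.zeros((1, 10))
    one_hot[0, 4] = 2.0
    p = subcortical_weighted_manifold(one_hot, man)
    assert p.values[0] == pytest.approx(man.coords[4].mean())
    with pytest.raises(ValueError, match="zero"):
        subcortical_weighted_manifold(np.zeros((1, 10)), man)


def test_explained_variance():
    assert np.allclose(explained_variance(np.array([2.0, 1.0, 1.0])),
                       [0.5, 0.25, 0.25])
    assert explained_variance(np.array([3.0])) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        explained_variance(np.zeros(3))
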