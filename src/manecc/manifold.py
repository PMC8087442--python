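"""Connectome manifolds: affinity kernel, diffusion-map and PCA embeddings,
Procrustes alignment, manifold eccentricity, and subcortical projection.

The embedding follows the diffusion-map construction: a normalized-angle
(cosine-derived) affinity between row connectivity profiles, anisotropic
density normalization with exponent ``alpha``, row-normalization to a Markov
operator, and spectral decomposition via the symmetric conjugate operator.
``alpha = 0.5`` and diffusion time ``t = 0`` (multiscale scaling
lambda/(1 - lambda)) are the defaults; they retain global relations between
data points.  Per-parcel *manifold eccentricity* is the Euclidean distance of
an aligned individual's coordinates from the template-manifold centroid over
the first three components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .datatypes import Connectome


@dataclass
class AffinityMatrix:
    values: np.ndarray  # parcels x parcels, in [0, 1], diagonal 1
    kernel: str = "normalized_angle"
    row_sparsity: float = 0.9


@dataclass
class Manifold:
    """Per-parcel eigenvector coordinates with their spectrum and parameters."""

    coords: np.ndarray  # parcels x k, trivial eigenvector excluded
    eigenvalues: np.ndarray  # nontrivial lambdas, descending
    alpha: float = 0.5
    t: float = 0.0
    variance_explained: np.ndarray = field(default_factory=lambda: np.array([]))
    method: str = "diffusion_map"
    aligned_to: Optional[str] = None

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class TemplateCenter:
    center: np.ndarray  # length = eccentricity component count


@dataclass
class EccentricityMap:
    values: np.ndarray  # per-parcel, >= 0
    n_components_used: int = 3


@dataclass
class SubcorticalProjection:
    values: np.ndarray  # one scalar per subcortical region
    weights_normalized: bool = True


def normalized_angle_affinity(conn: Connectome,
                              row_sparsity: float = 0.9) -> AffinityMatrix:
    """Cosine-angle affinity between row-sparsified connectivity profiles.

    Per row, the weakest ``row_sparsity`` fraction of entries is zeroed
    before computing cosine similarity; affinity = 1 - arccos(cos)/pi.
    """
    if not conn.log_transformed:
        raise ValueError("affinity expects a log-transformed connectome")
    if not (0 <= row_sparsity < 1):
        raise ValueError("row_sparsity must be in [0, 1)")
    w = conn.weights.copy()
    n = w.shape[0]
    if row_sparsity > 0:
        n_zero = int(np.floor(row_sparsity * n))
        if n_zero > 0:
            part = np.argpartition(w, n_zero - 1, axis=1)[:, :n_zero]
            rows = np.repeat(np.arange(n), n_zero)
            w[rows, part.ravel()] = 0.0
    norms = np.linalg.norm(w, axis=1)
    dead = np.flatnonzero(norms == 0)
    if len(dead):
        raise ValueError(f"all-zero connectivity profile for parcel row(s) {dead.tolist()}")
    cos = np.clip((w @ w.T) / np.outer(norms, norms), -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(values=0.5 * (aff + aff.T), row_sparsity=row_sparsity)


def _check_connected(a: np.ndarray) -> None:
    n_comp, _ = connected_components((a > 0).astype(np.int8), directed=False)
    if n_comp > 1:
        raise ValueError(f"affinity graph is disconnected ({n_comp} components)")


def diffusion_map_embed(aff: AffinityMatrix, alpha: float = 0.5, t: float = 0.0,
                        k: int = 3, multiscale: bool = True) -> Manifold:
    """Diffusion-map embedding of an affinity matrix.

    Density-normalizes A by (d_i d_j)^alpha, row-normalizes to a Markov
    operator, and eigendecomposes through the symmetric conjugate for
    stability.  Coordinates are psi_i * lambda_i^t for t > 0; at t = 0 the
    multiscale scaling lambda/(1 - lambda) is used (or no scaling when
    ``multiscale`` is off).  The trivial constant eigenvector is discarded and
    each component's sign is fixed so its largest-magnitude entry is positive.
    """
    a = np.asarray(aff.values, float)
    _check_connected(a)
    d = a.sum(axis=1)
    if alpha != 0:
        a = a / np.outer(d**alpha, d**alpha)
    drow = a.sum(axis=1)
    # symmetric conjugate S = D^-1/2 W D^-1/2 shares eigenvalues with D^-1 W
    s = a / np.sqrt(np.outer(drow, drow))
    s = 0.5 * (s + s.T)
    n = s.shape[0]
    if k >= n:
        raise ValueError(f"k={k} exceeds available nontrivial components ({n - 1})")
    evals, evecs = eigh(s)
    order = np.argsort(evals, kind="stable")[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(drow)[:, None]
    psi = psi / np.linalg.norm(psi[:, 0]) / np.sign(psi[0, 0])  # trivial ~ constant
    lam, psi = evals[1:k + 1], psi[:, 1:k + 1]
    if t > 0:
        scale = lam**t
    elif multiscale:
        scale = lam / (1.0 - np.clip(lam, None, 1 - 1e-12))
    else:
        scale = np.ones_like(lam)
    coords = psi * scale
    coords = _fix_signs(coords)
    var = explained_variance(np.maximum(evals[1:], 0.0))[:k]
    return Manifold(coords=coords, eigenvalues=lam, alpha=alpha, t=t,
                    variance_explained=var, method="diffusion_map")


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    out = coords.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_embed(conn: Connectome | AffinityMatrix, k: int = 3) -> Manifold:
    """Principal-component embedding of a row-profile matrix.

    Accepts either a log-transformed connectome (raw connectivity profiles)
    or an affinity matrix; passing the same normalized-angle affinity used
    for the diffusion map makes PCA a drop-in alternative decomposition of
    the identical kernel, the comparison the sensitivity analyses use.
    """
    if isinstance(conn, AffinityMatrix):
        profiles = conn.values
    else:
        if not conn.log_transformed:
            raise ValueError("embedding expects a log-transformed connectome")
        profiles = conn.weights
    x = profiles - profiles.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((sv > sv[0] * 1e-12).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    ev = sv**2
    coords = _fix_signs(u[:, :k] * sv[:k])
    return Manifold(coords=coords, eigenvalues=ev[:k],
                    variance_explained=ev[:k] / ev.sum(), method="pca")


def procrustes_align(source: Manifold, template: Manifold,
                     template_id: str = "template") -> Manifold:
    """Orthogonally rotate/reflect source coordinates onto the template.

    No scaling and no translation; the transform is the closed-form solution
    from the singular decomposition of template' . source.
    """
    if source.k != template.k:
        raise ValueError("component count mismatch between source and template")
    if source.coords.shape[0] != template.coords.shape[0]:
        raise ValueError("parcel count mismatch between source and template")
    r, _ = orthogonal_procrustes(source.coords, template.coords)
    return replace(source, coords=source.coords @ r, aligned_to=template_id)


def alignment_quality(aligned: Manifold, template: Manifold) -> np.ndarray:
    """Pearson r per component between aligned and template coordinates.

    Zero-variance components yield NaN (undefined correlation).
    """
    out = np.full(template.k, np.nan)
    for j in range(template.k):
        a, b = aligned.coords[:, j], template.coords[:, j]
        if a.std() == 0 or b.std() == 0:
            continue
        out[j] = np.corrcoef(a, b)[0, 1]
    return out


def flag_poor_alignment(qualities: list[np.ndarray],
                        exclude_fraction: float = 0.1) -> np.ndarray:
    """Indices of the subjects with the lowest mean per-component r."""
    mean_r = np.array([np.nanmean(q) for q in qualities])
    n_flag = int(np.ceil(exclude_fraction * len(mean_r)))
    return np.argsort(mean_r, kind="stable")[:n_flag]


def template_center(template: Manifold, n_components: int = 3) -> TemplateCenter:
    """Centroid of the template manifold over the first n components."""
    if n_components > template.k:
        raise ValueError("n_components exceeds available components")
    return TemplateCenter(center=template.coords[:, :n_components].mean(axis=0))


def manifold_eccentricity(individual: Manifold, center: TemplateCenter,
                          n_components: Optional[int] = None,
                          require_aligned: bool = True) -> EccentricityMap:
    """Per-parcel Euclidean distance from the template center.

    Uses the first ``n_components`` coordinates (default: the center's
    length, 3 in the standard analysis; pass k for the all-eigenvector
    variant, in which case the center must match).
    """
    if require_aligned and individual.aligned_to is None:
        raise ValueError("individual manifold must be aligned to the template")
    nc = len(center.center) if n_components is None else n_components
    if nc > individual.k or nc != len(center.center):
        raise ValueError("component count mismatch with the template center")
    diff = individual.coords[:, :nc] - center.center
    return EccentricityMap(values=np.sqrt((diff**2).sum(axis=1)),
                           n_components_used=nc)


def subcortical_weighted_manifold(subcortico_cortical: np.ndarray,
                                  cortical: Manifold,
                                  normalize: bool = True) -> SubcorticalProjection:
    """Project subcortico-cortical streamline strengths into the manifold.

    For subcortical region s and component e, M(s, e) = sum_j w(s, j) E_e(j)
    with per-region weight normalization by default; the returned scalar per
    region is the mean of M(s, .) over components.
    """
    w = np.atleast_2d(np.asarray(subcortico_cortical, float))
    if (w < 0).any():
        raise ValueError("subcortico-cortical weights must be nonnegative")
    if w.shape[1] != cortical.coords.shape[0]:
        raise ValueError("weight columns must match cortical parcel count")
    totals = w.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if len(dead):
        raise ValueError(f"all-zero weight row for subcortical region(s) {dead.tolist()}")
    if normalize:
        w = w / totals[:, None]
    m = w @ cortical.coords  # regions x components
    return SubcorticalProjection(values=m.mean(axis=1), weights_normalized=normalize)


def explained_variance(eigenvalues: np.ndarray) -> np.ndarray:
    """Per-component fraction lambda_i / sum(lambda) of the nontrivial spectrum."""
    lam = np.asarray(eigenvalues, float)
    if (lam < 0).any():
        raise ValueError("eigenvalues must be nonnegative")
    total = lam.sum()
    if total == 0:
        raise ValueError("all-zero spectrum")
    return lam / total
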