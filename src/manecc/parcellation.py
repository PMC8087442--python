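"""Synthetic cortical/subcortical parcellation on the unit sphere.

The analysis operates on parcel-wise matrices; all the geometry it needs is a
spherical centroid per cortical parcel, a hemisphere label, a functional
community, a hierarchy class, and parcel adjacency.  This module fabricates a
parcellation with those properties: two mirror-symmetric hemispheres of
quasi-uniform centroids, seven spatially contiguous functional communities,
four latitude-band hierarchy classes, and a symmetrized k-nearest-neighbour
adjacency graph that is connected within each hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

COMMUNITIES = ("visual", "somatomotor", "dorsal_attention", "ventral_attention",
               "limbic", "frontoparietal", "default_mode")
HIERARCHIES = ("idiotypic", "unimodal", "heteromodal", "paralimbic")
SUBCORTICAL_NAMES = ("accumbens", "amygdala", "caudate", "hippocampus",
                     "pallidum", "putamen", "thalamus")


@dataclass
class ParcelTable:
    """Parcel metadata: one row per parcel plus an adjacency structure.

    ``table`` columns: parcel_id, name, hemisphere (L/R), x, y, z (unit-sphere
    centroid for cortical parcels), community, hierarchy, structure
    (cortical/subcortical).  ``neighbors`` maps cortical parcel_id -> sorted
    list of adjacent cortical parcel_ids (symmetric, no self-loops).
    """

    table: pd.DataFrame
    neighbors: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def cortical_ids(self) -> np.ndarray:
        return self.table.loc[self.table.structure == "cortical", "parcel_id"].to_numpy()

    @property
    def subcortical_ids(self) -> np.ndarray:
        return self.table.loc[self.table.structure == "subcortical", "parcel_id"].to_numpy()

    @property
    def n_cortical(self) -> int:
        return len(self.cortical_ids)

    def coords(self, ids=None) -> np.ndarray:
        """Centroid coordinates (n x 3), cortical parcels by default."""
        sub = self.table if ids is None else self.table.set_index("parcel_id").loc[ids].reset_index()
        return sub[["x", "y", "z"]].to_numpy(float)

    def cortical_coords(self) -> np.ndarray:
        return self.coords(self.cortical_ids)

    def great_circle_distances(self) -> np.ndarray:
        """Pairwise great-circle (arc) distances between cortical centroids."""
        xyz = self.cortical_coords()
        cos = np.clip(xyz @ xyz.T, -1.0, 1.0)
        return np.arccos(cos)

    def validate(self) -> None:
        cort = self.table[self.table.structure == "cortical"]
        norms = np.linalg.norm(cort[["x", "y", "z"]].to_numpy(float), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("cortical centroids must lie on the unit sphere")
        for i, nbrs in self.neighbors.items():
            if i in nbrs:
                raise ValueError(f"parcel {i} listed as its own neighbor")
            for j in nbrs:
                if i not in self.neighbors.get(j, []):
                    raise ValueError(f"adjacency not symmetric: {i}->{j}")


def _hemisphere_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform points on the left (x <= 0) half of the unit sphere.

    Fibonacci lattice in (z, azimuth) with the azimuth confined to the
    half-circle, plus a small seeded jitter so distinct seeds give distinct
    (but equally uniform) layouts.
    """
    k = np.arange(n)
    z = -1.0 + (2.0 * k + 1.0) / n  # midpoints, avoids exact poles
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # azimuth in (pi/2, 3pi/2) => x = cos(phi) <= 0
    phi = np.pi / 2.0 + np.pi * ((k / golden) % 1.0)
    z = np.clip(z + rng.normal(0.0, 0.5 / n, n), -1 + 1e-6, 1 - 1e-6)
    r = np.sqrt(1.0 - z**2)
    xyz = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    xyz[:, 0] = -np.abs(xyz[:, 0])  # keep strictly in the left hemisphere
    return xyz / np.linalg.norm(xyz, axis=1, keepdims=True)


def _contiguous_communities(xyz: np.ndarray, n_comm: int, rng: np.random.Generator) -> np.ndarray:
    """Assign spatially contiguous patches by nearest of n_comm seed centroids."""
    seeds = xyz[rng.choice(len(xyz), size=n_comm, replace=False)]
    for _ in range(25):  # Lloyd iterations on the sphere keep patches compact
        lab = np.argmin(cdist(xyz, seeds), axis=1)
        for c in range(n_comm):
            mask = lab == c
            if mask.any():
                m = xyz[mask].mean(axis=0)
                seeds[c] = m / np.linalg.norm(m)
    # guarantee every community label occurs
    lab = np.argmin(cdist(xyz, seeds), axis=1)
    for c in range(n_comm):
        if not (lab == c).any():
            lab[np.argmin(cdist(xyz, seeds[c][None]))] = c
    return lab


def _knn_adjacency(xyz: np.ndarray, k: int) -> list[set[int]]:
    d = cdist(xyz, xyz)
    np.fill_diagonal(d, np.inf)
    nbrs = [set(np.argsort(d[i])[:k].tolist()) for i in range(len(xyz))]
    for i in range(len(xyz)):  # symmetrize
        for j in list(nbrs[i]):
            nbrs[j].add(i)
    # connect any stray components through their closest inter-component pair
    while True:
        comp = _components(nbrs)
        if len(comp) == 1:
            break
        a, b = comp[0], comp[1]
        ia, jb = min(((i, j) for i in a for j in b), key=lambda t: d[t])
        nbrs[ia].add(jb)
        nbrs[jb].add(ia)
    return nbrs


def _components(nbrs: list[set[int]]) -> list[list[int]]:
    seen, comps = set(), []
    for s in range(len(nbrs)):
        if s in seen:
            continue
        stack, comp = [s], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(nbrs[v] - seen)
        comps.append(comp)
    return comps


def simulate_parcellation(n_cortical: int = 200, n_subcortical: int = 14,
                          seed: int = 0, k_neighbors: int = 6) -> ParcelTable:
    """Build a synthetic parcellation table.

    Cortical parcels are split evenly across hemispheres (n_cortical must be
    even and >= 14 so that seven communities and four hierarchy bands fit);
    the right hemisphere mirrors the left (x -> -x), and community/hierarchy
    labels are mirrored with the centroids.
    """
    if n_cortical % 2 != 0:
        raise ValueError("n_cortical must be even (split across hemispheres)")
    if n_cortical < 14:
        raise ValueError("n_cortical must be >= 14")
    if n_subcortical < 0:
        raise ValueError("n_subcortical must be >= 0")
    rng = np.random.default_rng(seed)
    n_half = n_cortical // 2
    left = _hemisphere_points(n_half, rng)
    comm = _contiguous_communities(left, len(COMMUNITIES), rng)
    # hierarchy: four contiguous latitude bands (quartiles of z)
    qs = np.quantile(left[:, 2], [0.25, 0.5, 0.75])
    hier = np.searchsorted(qs, left[:, 2])

    rows = []
    for hemi_idx, hemi in enumerate("LR"):
        for i in range(n_half):
            x, y, z = left[i]
            if hemi == "R":
                x = -x
            rows.append(dict(parcel_id=hemi_idx * n_half + i,
                             name=f"ctx_{hemi}_{i:03d}", hemisphere=hemi,
                             x=x, y=y, z=z,
                             community=COMMUNITIES[comm[i]],
                             hierarchy=HIERARCHIES[hier[i]],
                             structure="cortical"))
    for s in range(n_subcortical):
        base = SUBCORTICAL_NAMES[(s // 2) % len(SUBCORTICAL_NAMES)]
        hemi = "LR"[s % 2]
        rows.append(dict(parcel_id=n_cortical + s, name=f"sctx_{base}_{hemi}",
                         hemisphere=hemi, x=0.0, y=0.0, z=0.0,
                         community="none", hierarchy="none",
                         structure="subcortical"))
    table = pd.DataFrame(rows)

    neighbors: dict[int, list[int]] = {}
    for hemi_idx in range(2):
        off = hemi_idx * n_half
        nbrs = _knn_adjacency(left, k_neighbors)
        for i, s in enumerate(nbrs):
            neighbors[off + i] = sorted(off + j for j in s)
    pt = ParcelTable(table=table, neighbors=neighbors)
    pt.validate()
    return pt
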