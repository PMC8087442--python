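"""Synthetic longitudinal cohort generator.

Emulates an accelerated longitudinal two-visit imaging study: baseline ages
spread over five equal strata (14-25 y by default), a ~6-12 month follow-up
interval, three acquisition sites, balanced sexes, and per-visit head-motion
nuisance.  Connectomes follow a lognormal edge model with exponential distance
decay, a within-community bonus, a smooth latitude-like connectivity gradient,
subject-specific random intercepts, site offsets, and motion-scaled noise.
An age-related multiplicative strengthening is injected into within-community
edges of a designated "expanding" (transmodal) parcel set, the ground truth
that downstream detection experiments recover.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .datatypes import Connectome, VisitRecord
from .parcellation import COMMUNITIES, ParcelTable

N_STRATA = 5


@dataclass
class CohortConfig:
    """Generator parameters; defaults reflect the study design being emulated.

    Edge model for cortico-cortical log-weights (parcels i, j):
        log w = a0 - d_ij/distance_scale + community_bonus*[comm_i == comm_j]
                + gradient_bonus*(1 - |g_i - g_j|)
                + beta_age*(age - age_ref)*[i, j in expanding set, same community]
                + site_offset + subject_intercept + eps,
        eps ~ N(0, (sigma_noise*(1 + motion))^2),
    with d the great-circle centroid distance and g the centroid z-coordinate
    (a smooth hemisphere-symmetric gradient).  Weights are exp(log w),
    symmetric, zero-diagonal, and the weakest (1 - density) fraction of edges
    is pruned to zero.
    """

    n_subjects: int = 208
    age_range: tuple[float, float] = (14.0, 25.0)  # baseline ages, years
    n_sites: int = 3
    interval_range: tuple[float, float] = (0.5, 1.0)  # years
    n_cortical: int = 200
    n_subcortical: int = 14
    expanding_set: Optional[Sequence[int]] = None  # default: heteromodal parcels
    beta_age: float = 0.02  # per-year log-weight strengthening
    beta_age_subcortical: float = 0.02  # caudate/thalamus rows, per-year
    age_ref: float = 20.0  # mid-range reference, decouples intercept from slope
    sigma_subject: float = 0.15  # subject random-intercept SD (log-weight units)
    sigma_noise: float = 0.25  # edge noise SD (log-weight units)
    site_offsets: tuple[float, ...] = (0.0, 0.1, -0.1)
    a0: float = 1.0
    distance_scale: float = 0.8  # radians of arc
    community_bonus: float = 0.8
    gradient_bonus: float = 0.6
    density: float = 0.35  # fraction of cortico-cortical edges retained
    subcortical_a0: float = 0.5
    subcortical_community_bonus: float = 0.8
    iq_coeffs: tuple[float, ...] = (5.0, 5.0)
    iq_intercept: float = 100.0
    iq_sigma: float = 10.0
    tanner_fraction: float = 0.35  # subjects with a baseline Tanner score
    motion_mean: float = 0.15  # mm
    motion_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0 < self.interval_range[0] <= self.interval_range[1] <= 2):
            raise ValueError("interval_range must lie within (0, 2] years")
        for name in ("sigma_subject", "sigma_noise", "iq_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if len(self.site_offsets) < self.n_sites:
            raise ValueError("site_offsets must cover n_sites")


def resolve_expanding_set(parcels: ParcelTable, config: CohortConfig) -> np.ndarray:
    """Expanding parcel ids: configured set, or all heteromodal parcels."""
    if config.expanding_set is not None:
        ids = np.asarray(sorted(config.expanding_set), dtype=int)
        if not np.isin(ids, parcels.cortical_ids).all():
            raise ValueError("expanding_set must be a subset of cortical parcel ids")
        return ids
    t = parcels.table
    return t.loc[(t.structure == "cortical") & (t.hierarchy == "heteromodal"),
                 "parcel_id"].to_numpy()


def simulate_cohort(config: CohortConfig) -> list[VisitRecord]:
    """Draw the visit table: two visits per subject, stratified design.

    Baseline ages are uniform within five equal strata spanning ``age_range``;
    subjects rotate through strata, sexes alternate within each stratum
    (balanced to +-1), and sites are assigned round-robin.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0)))
    lo, hi = config.age_range
    edges = np.linspace(lo, hi, N_STRATA + 1)
    records: list[VisitRecord] = []
    sex_counter = [0] * N_STRATA
    tanner_ids = set(
        rng.choice(config.n_subjects,
                   size=int(round(config.tanner_fraction * config.n_subjects)),
                   replace=False).tolist())
    for s in range(config.n_subjects):
        stratum = s % N_STRATA
        sex = "MF"[sex_counter[stratum] % 2]
        sex_counter[stratum] += 1
        site = f"site{s % config.n_sites + 1}"
        age0 = rng.uniform(edges[stratum], edges[stratum + 1])
        interval = rng.uniform(*config.interval_range)
        tanner = None
        if s in tanner_ids:
            raw = 1 + 4 * (age0 - lo) / (hi - lo) + rng.normal(0, 0.5)
            tanner = int(np.clip(np.round(raw), 1, 5))
        for visit, age in (("baseline", age0), ("followup", age0 + interval)):
            motion = abs(rng.normal(config.motion_mean, config.motion_sd))
            records.append(VisitRecord(
                subject_id=f"sub-{s + 1:04d}", visit=visit, age=age, sex=sex,
                site=site, motion=motion,
                tanner=tanner if visit == "baseline" else None))
    return records


def subject_intercepts(config: CohortConfig) -> dict[str, float]:
    """Per-subject random intercepts, N(0, sigma_subject), seeded."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x51)))
    draws = rng.normal(0.0, config.sigma_subject, config.n_subjects)
    return {f"sub-{s + 1:04d}": float(draws[s]) for s in range(config.n_subjects)}


class _Geometry:
    """Precomputed edge-model terms that do not depend on subject or visit."""

    def __init__(self, parcels: ParcelTable, config: CohortConfig):
        self.parcels = parcels
        cids = parcels.cortical_ids
        self.n_c = len(cids)
        xyz = parcels.cortical_coords()
        d = parcels.great_circle_distances()
        comm = parcels.table.set_index("parcel_id").loc[cids, "community"].to_numpy()
        g = xyz[:, 2]
        same_comm = comm[:, None] == comm[None, :]
        self.base = (config.a0 - d / config.distance_scale
                     + config.community_bonus * same_comm
                     + config.gradient_bonus * (1.0 - np.abs(g[:, None] - g[None, :])))
        exp_ids = resolve_expanding_set(parcels, config)
        in_exp = np.isin(cids, exp_ids)
        self.age_mask = in_exp[:, None] & in_exp[None, :] & same_comm
        np.fill_diagonal(self.age_mask, False)
        # subcortical block: each region has a preferred cortical community
        sids = parcels.subcortical_ids
        self.n_s = len(sids)
        names = parcels.table.set_index("parcel_id").loc[sids, "name"].astype(str)
        self.sc_age_rows = np.array(
            ["caudate" in n or "thalamus" in n for n in names], dtype=bool)
        sc_comm = np.array([COMMUNITIES[s % len(COMMUNITIES)] for s in range(self.n_s)])
        sc_same = sc_comm[:, None] == comm[None, :]
        self.sc_base = (config.subcortical_a0
                        + config.subcortical_community_bonus * sc_same)
        # carrier rows strengthen their preferred-community projections with
        # age; a uniform whole-row gain would cancel under weight
        # normalization in the manifold projection
        self.sc_age_mask = self.sc_age_rows[:, None] & sc_same
        self.iu = np.triu_indices(self.n_c, k=1)


_GEOM_CACHE: dict[tuple, _Geometry] = {}


def _geometry(parcels: ParcelTable, config: CohortConfig) -> _Geometry:
    xyz = parcels.table[["x", "y", "z"]].to_numpy(float)
    key = (hash(xyz.tobytes()), repr(config))
    if key not in _GEOM_CACHE:
        _GEOM_CACHE.clear()  # keep at most one cohort's geometry alive
        _GEOM_CACHE[key] = _Geometry(parcels, config)
    return _GEOM_CACHE[key]


def simulate_connectome(parcels: ParcelTable, visit: VisitRecord,
                        config: CohortConfig, subject_intercept: float = 0.0,
                        rng: Optional[np.random.Generator] = None) -> Connectome:
    """Generate one visit's connectome under the lognormal edge model.

    Deterministic given (config.seed, subject_id, visit) unless an explicit
    ``rng`` is supplied.
    """
    geo = _geometry(parcels, config)
    if rng is None:
        tag = zlib.crc32(f"{visit.subject_id}|{visit.visit}".encode())
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xED, tag)))
    site_idx = int(visit.site.replace("site", "")) - 1
    offset = config.site_offsets[site_idx] + subject_intercept
    noise_sd = config.sigma_noise * (1.0 + visit.motion)

    logw = geo.base + offset
    if config.beta_age != 0.0:
        logw = logw + config.beta_age * (visit.age - config.age_ref) * geo.age_mask
    eps = np.zeros_like(logw)
    eps[geo.iu] = rng.normal(0.0, noise_sd, len(geo.iu[0]))
    logw = logw + eps + eps.T
    w = np.exp(logw)
    np.fill_diagonal(w, 0.0)
    if config.density < 1.0:
        vals = w[geo.iu]
        thr = np.quantile(vals, 1.0 - config.density)
        w[w < thr] = 0.0
        w = np.minimum(w, w.T)  # keep exact symmetry after pruning

    n = geo.n_c + geo.n_s
    full = np.zeros((n, n))
    full[:geo.n_c, :geo.n_c] = w
    if geo.n_s:
        sc = geo.sc_base + offset
        if config.beta_age_subcortical != 0.0:
            sc = sc + (config.beta_age_subcortical * (visit.age - config.age_ref)
                       * geo.sc_age_mask)
        sc = sc + rng.normal(0.0, noise_sd, sc.shape)
        sc = np.exp(sc)
        full[geo.n_c:, :geo.n_c] = sc
        full[:geo.n_c, geo.n_c:] = sc.T
    conn = Connectome(weights=full,
                      parcel_ids=np.concatenate([parcels.cortical_ids,
                                                 parcels.subcortical_ids]))
    return conn


def simulate_iq(features: np.ndarray, config: CohortConfig,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """IQ scores: intercept + features . iq_coeffs + Gaussian noise."""
    features = np.atleast_2d(np.asarray(features, float))
    coeffs = np.asarray(config.iq_coeffs, float)
    if features.shape[1] != len(coeffs):
        raise ValueError(
            f"feature count {features.shape[1]} does not match "
            f"iq_coeffs length {len(coeffs)}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x10)))
    return (config.iq_intercept + features @ coeffs
            + rng.normal(0.0, config.iq_sigma, features.shape[0]))


def null_config(config: CohortConfig) -> CohortConfig:
    """Copy of a config with all injected age effects switched off."""
    return replace(config, beta_age=0.0, beta_age_subcortical=0.0)
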