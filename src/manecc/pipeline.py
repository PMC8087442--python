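"""End-to-end orchestration: cohort -> template -> manifolds -> eccentricity
-> mixed-effects age model -> graph context -> prediction.

Every randomized stage consumes a seed derived deterministically from the
single global seed and the stage name, so reruns with the same configuration
reproduce identical outputs while stages stay statistically independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .cohort import (CohortConfig, resolve_expanding_set, simulate_cohort,
                     simulate_connectome, simulate_iq, subject_intercepts)
from .datatypes import VisitRecord, visits_to_frame
from .graph import (cluster_change_correlations, consensus_partition,
                    contiguous_clusters, degree_centrality, louvain_partition,
                    participation_coefficient, within_module_degree,
                    connectivity_distance)
from .lme import fit_lme_per_feature, stratify_map
from .manifold import (Manifold, alignment_quality, diffusion_map_embed,
                       manifold_eccentricity, normalized_angle_affinity,
                       pca_embed, procrustes_align, subcortical_weighted_manifold,
                       template_center)
from .parcellation import ParcelTable, simulate_parcellation
from .predict import nested_elasticnet_predict
from .template import distance_dependent_group, log_transform

logger = logging.getLogger("manecc")


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific seed below 2^31, stable across runs."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Full pipeline configuration with defaults for every stage."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_template: int | None = None  # default: ~15% of subjects
    n_components: int = 3
    alpha: float = 0.5
    t: float = 0.0
    row_sparsity: float = 0.9
    embed_method: str = "dm"  # dm | pca
    n_bins: int = 10
    q_threshold: float = 0.05
    gamma: float = 1.0
    louvain_restarts: int = 10
    n_perm: int = 200
    prediction_reps: int = 10
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["cohort"] = dict(self.cohort.__dict__)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            for key in ("age_range", "interval_range", "site_offsets", "iq_coeffs"):
                if key in cohort and isinstance(cohort[key], list):
                    cohort[key] = tuple(cohort[key])
            cohort = CohortConfig(**cohort)
        return cls(cohort=cohort, **d)


def split_template_cohort(visits: list[VisitRecord], n_template: int, seed: int = 0):
    """Stratified template/analysis split matched on age stratum, sex, site."""
    vdf = visits_to_frame(visits)
    base = vdf[vdf.visit == "baseline"].reset_index(drop=True)
    n_subj = len(base)
    if n_template >= n_subj:
        raise ValueError("n_template must be smaller than the cohort")
    if n_template == 0:
        return [], sorted(base.subject_id)
    stratum = pd.cut(base.age, bins=5, labels=False)
    cells = base.assign(stratum=stratum).groupby(
        ["stratum", "sex", "site"], observed=True)
    rng = np.random.default_rng(seed)
    shares = {}
    for key, grp in cells:
        shares[key] = n_template * len(grp) / n_subj
    # largest-remainder allocation of the template quota across cells
    alloc = {k: int(np.floor(v)) for k, v in shares.items()}
    remainder = n_template - sum(alloc.values())
    for k in sorted(shares, key=lambda k: shares[k] - alloc[k], reverse=True)[:remainder]:
        alloc[k] += 1
    template_ids: list[str] = []
    for key, grp in cells:
        take = min(alloc.get(key, 0), len(grp))
        if take:
            template_ids += list(rng.choice(grp.subject_id, size=take, replace=False))
    if len(template_ids) < n_template:
        raise ValueError("could not fill the template quota with matched strata")
    template_ids = sorted(template_ids)
    analysis_ids = sorted(set(base.subject_id) - set(template_ids))
    return template_ids, analysis_ids


def _embed(conn_log, config: RunConfig) -> Manifold:
    aff = normalized_angle_affinity(conn_log, row_sparsity=config.row_sparsity)
    if config.embed_method == "pca":  # same kernel, alternative decomposition
        return pca_embed(aff, k=config.n_components)
    return diffusion_map_embed(aff, alpha=config.alpha, t=config.t,
                               k=config.n_components)


def compute_manifold_features(parcels: ParcelTable, visits: list[VisitRecord],
                              config: RunConfig):
    """Template manifold plus aligned per-visit eccentricity and subcortical
    features for the analysis (non-template) cohort.

    Returns a dict with the analysis visit table, the eccentricity matrix
    (rows aligned to it), subcortical projections, alignment qualities, the
    template manifold/center, per-visit log connectomes, and the split.
    """
    cohort = config.cohort
    intercepts = subject_intercepts(cohort)
    n_subj = cohort.n_subjects
    n_template = config.n_template
    if n_template is None:
        n_template = max(4, round(0.15 * n_subj))
    template_ids, analysis_ids = split_template_cohort(
        visits, n_template, seed=derive_seed(config.seed, "split"))
    assert not set(template_ids) & set(analysis_ids)

    by_subject: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_subject.setdefault(v.subject_id, []).append(v)

    n_c = parcels.n_cortical
    template_conns = []
    for sid in template_ids:
        for v in by_subject[sid]:
            if v.visit != "baseline":
                continue
            conn = simulate_connectome(parcels, v, cohort, intercepts[sid])
            cc = log_transform(_cortical_block(conn, n_c))
            template_conns.append(cc)
    if template_conns:
        group = distance_dependent_group(template_conns, parcels,
                                         n_bins=config.n_bins)
        template_conn = group.connectome
    else:
        raise ValueError("template cohort is empty")
    template = _embed(template_conn, config)
    center = template_center(template, n_components=config.n_components)

    rows, ecc, subc, quality = [], [], [], []
    for sid in analysis_ids:
        for v in sorted(by_subject[sid], key=lambda r: r.age):
            conn = simulate_connectome(parcels, v, cohort, intercepts[sid])
            conn_log = log_transform(conn)
            cort = _cortical_block(conn_log, n_c)
            man = _embed(cort, config)
            aligned = procrustes_align(man, template)
            quality.append(alignment_quality(aligned, template))
            ecc.append(manifold_eccentricity(aligned, center).values)
            if parcels.n_parcels > n_c:
                sc_block = conn_log.weights[n_c:, :n_c]
                subc.append(subcortical_weighted_manifold(sc_block, aligned).values)
            rows.append(v)
    return dict(
        visits=rows, visits_df=visits_to_frame(rows),
        eccentricity=np.asarray(ecc),
        subcortical=np.asarray(subc) if subc else None,
        alignment=np.asarray(quality),
        template=template, center=center, template_connectome=template_conn,
        template_ids=template_ids, analysis_ids=analysis_ids)


def designate_expanding_community(parcels: ParcelTable, seed: int = 0,
                                  size_range: tuple[int, int] = (24, 36),
                                  n_pilot: int = 60) -> str:
    """Designate the synthetic 'transmodal' community for effect injection.

    Not every community makes a well-posed expansion experiment: a community
    sitting at the template-manifold center cannot move away from it, and a
    community with strong leverage on the global embedding drags near-center
    parcels along (their eccentricity grows from ~0, registering as spurious
    expansion).  Mirroring a power analysis, each candidate community of
    roughly the target size is screened with one small pilot cohort; the
    designated community is the one whose detected expansion is most
    confined to the injected set (highest sensitivity, then least
    spillover).  The screening cohorts are independent of any cohort later
    analyzed.
    """
    from .lme import fit_lme_per_feature
    t = parcels.table
    cort = t[t.structure == "cortical"]
    sizes = cort.groupby("community").size()
    candidates = [c for c in sizes.index
                  if size_range[0] <= sizes[c] <= size_range[1]]
    if not candidates:
        mid = sum(size_range) / 2
        candidates = [sizes.index[np.argmin(np.abs(sizes.values - mid))]]
    scores = {}
    for comm in candidates:
        exp_ids = cort.loc[cort.community == comm, "parcel_id"].to_numpy()
        cohort = CohortConfig(n_subjects=n_pilot,
                              n_cortical=parcels.n_cortical, n_subcortical=0,
                              expanding_set=tuple(int(x) for x in exp_ids),
                              seed=derive_seed(seed, f"pilot-{comm}"))
        rc = RunConfig(cohort=cohort, seed=derive_seed(seed, f"pilot-{comm}"))
        feats = compute_manifold_features(parcels, simulate_cohort(cohort), rc)
        res = fit_lme_per_feature(feats["eccentricity"], feats["visits_df"],
                                  feature_ids=parcels.cortical_ids)
        tab = res.table
        pos = set(tab[(tab.significant) & (tab.t > 0)].feature_id)
        es = set(int(x) for x in exp_ids)
        sens = len(pos & es) / len(es)
        spill = len(pos - es) / len(es)
        scores[comm] = sens - spill
    return max(sorted(scores), key=lambda c: scores[c])


def _cortical_block(conn, n_c):
    from .datatypes import Connectome
    return Connectome(weights=conn.weights[:n_c, :n_c],
                      parcel_ids=conn.parcel_ids[:n_c],
                      log_transformed=conn.log_transformed)


def subject_deltas(visits_df: pd.DataFrame, features: np.ndarray):
    """Follow-up minus baseline feature change per subject (sorted ids)."""
    sids = sorted(visits_df.subject_id.unique())
    out = np.empty((len(sids), features.shape[1]))
    for i, sid in enumerate(sids):
        rows = visits_df.index[visits_df.subject_id == sid]
        sub = visits_df.loc[rows]
        b = rows[sub.visit == "baseline"][0]
        f = rows[sub.visit == "followup"][0]
        out[i] = features[f] - features[b]
    return sids, out


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write results under the run directory."""
    if config.out_dir is None:
        raise ValueError("config.out_dir is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    manifest: dict = {"config": config.to_dict(), "outputs": {}}
    try:
        cohort = config.cohort
        logger.info("simulating parcellation and cohort (seed=%d)", config.seed)
        parcels = simulate_parcellation(cohort.n_cortical, cohort.n_subcortical,
                                        seed=derive_seed(config.seed, "parcels"))
        visits = simulate_cohort(cohort)
        mio.write_parcel_table(parcels, out / "parcels.tsv")

        logger.info("computing template and individual manifolds")
        feats = compute_manifold_features(parcels, visits, config)
        vdf = feats["visits_df"]
        ecc = feats["eccentricity"]
        np.savetxt(out / "eccentricity.tsv", ecc, delimiter="\t", fmt="%.10g")

        logger.info("fitting per-region mixed-effects age models")
        lme_res = fit_lme_per_feature(ecc, vdf,
                                      feature_ids=parcels.cortical_ids,
                                      q_threshold=config.q_threshold)
        mio.write_result_table(lme_res.table, out / "lme_eccentricity.tsv")

        cids = parcels.cortical_ids
        tmap = lme_res.table.t.to_numpy()
        meta = parcels.table.set_index("parcel_id").loc[cids]
        strat_h = stratify_map(tmap, meta.hierarchy.to_numpy())
        strat_c = stratify_map(tmap, meta.community.to_numpy())
        strat_h.to_csv(out / "stratified_hierarchy.tsv", sep="\t", index=False)
        strat_c.to_csv(out / "stratified_community.tsv", sep="\t", index=False)

        if feats["subcortical"] is not None:
            sc_res = fit_lme_per_feature(
                feats["subcortical"], vdf,
                feature_ids=parcels.subcortical_ids,
                q_threshold=config.q_threshold)
            mio.write_result_table(sc_res.table, out / "lme_subcortical.tsv")

        logger.info("graph-theoretical contextualization")
        graph_df = _graph_stage(parcels, visits, feats, lme_res, config)
        if graph_df is not None:
            graph_df.to_csv(out / "cluster_change_correlations.tsv",
                            sep="\t", index=False)

        logger.info("IQ prediction stage")
        pred = _prediction_stage(parcels, feats, config, lme_res)
        if pred is not None:
            pd.DataFrame(dict(repetition=np.arange(len(pred.per_repetition_r)),
                              r=pred.per_repetition_r,
                              mae=pred.per_repetition_mae)).to_csv(
                out / "prediction_metrics.tsv", sep="\t", index=False)
            manifest["prediction"] = dict(
                mean_r=pred.mean_r, mean_mae=pred.mean_mae,
                baseline_r=pred.baseline_r, meng_z=pred.meng_z)

        manifest["n_significant_regions"] = int(lme_res.table.significant.sum())
        for f in sorted(out.glob("*.tsv")):
            manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return out
    except Exception as exc:  # mark partial outputs, re-raise with stage info
        (out / "failed").write_text(str(exc))
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()


def _graph_stage(parcels, visits, feats, lme_res, config: RunConfig):
    vdf = feats["visits_df"]
    ecc = feats["eccentricity"]
    n_c = parcels.n_cortical
    mask = lme_res.table.significant.to_numpy(bool)
    clusters = contiguous_clusters(mask, parcels)
    if clusters.max() == 0:
        return None
    cohort = config.cohort
    intercepts = subject_intercepts(cohort)
    seed = derive_seed(config.seed, "graph")
    dists = parcels.great_circle_distances()
    degree, wmd, part, cdist_ = [], [], [], []
    partitions = []
    conns = []
    for _, row in vdf.iterrows():
        v = next(x for x in visits if x.subject_id == row.subject_id
                 and x.visit == row.visit)
        conn = _cortical_block(
            simulate_connectome(parcels, v, cohort, intercepts[v.subject_id]), n_c)
        conns.append(conn)
        partitions.append(louvain_partition(conn, gamma=config.gamma, seed=seed,
                                            n_restarts=config.louvain_restarts))
    consensus = consensus_partition(partitions, seed=seed)
    for conn in conns:
        degree.append(degree_centrality(conn))
        wmd.append(within_module_degree(conn, consensus))
        part.append(participation_coefficient(conn, consensus))
        cdist_.append(connectivity_distance(conn, dists))
    sids, d_ecc = subject_deltas(vdf, ecc)
    metrics = dict(degree=np.asarray(degree), within_module_degree=np.asarray(wmd),
                   participation=np.asarray(part),
                   connectivity_distance=np.asarray(cdist_))
    delta_ecc_by_cluster = {}
    delta_metrics: dict[str, dict[int, np.ndarray]] = {m: {} for m in metrics}
    for cl in range(1, clusters.max() + 1):
        in_cl = clusters == cl
        delta_ecc_by_cluster[cl] = d_ecc[:, in_cl].mean(axis=1)
        for m, vals in metrics.items():
            _, d_m = subject_deltas(vdf, vals)
            with np.errstate(invalid="ignore"):
                delta_metrics[m][cl] = np.nanmean(d_m[:, in_cl], axis=1)
    return cluster_change_correlations(delta_ecc_by_cluster, delta_metrics,
                                       n_perm=config.n_perm,
                                       seed=derive_seed(config.seed, "perm"))


def _prediction_stage(parcels, feats, config: RunConfig, lme_res=None):
    vdf = feats["visits_df"]
    ecc = feats["eccentricity"]
    cohort = config.cohort
    exp_ids = resolve_expanding_set(parcels, cohort)
    in_exp = np.isin(parcels.cortical_ids, exp_ids)
    sids, d_ecc = subject_deltas(vdf, ecc)
    base_rows = vdf.index[vdf.visit == "baseline"]
    base_df = vdf.loc[base_rows].set_index("subject_id")
    base_ecc = pd.DataFrame(ecc[base_rows], index=base_df.index).loc[sids].to_numpy()
    latent = np.column_stack([base_ecc[:, in_exp].mean(axis=1),
                              d_ecc[:, in_exp].mean(axis=1)])
    latent_z = (latent - latent.mean(axis=0)) / latent.std(axis=0)
    rng = np.random.default_rng(derive_seed(config.seed, "iq"))
    iq = simulate_iq(latent_z, cohort, rng=rng)

    # features are the identified (age-significant) regions, as in the
    # analysis design; all regions if nothing was identified
    identified = np.ones(ecc.shape[1], bool)
    if lme_res is not None and lme_res.table.significant.any():
        identified = lme_res.table.significant.to_numpy(bool)
    features = np.column_stack([base_ecc[:, identified], d_ecc[:, identified]])
    covariates = np.column_stack([
        base_df.loc[sids, "age"].to_numpy(float),
        (base_df.loc[sids, "sex"] == "F").to_numpy(float),
        pd.get_dummies(base_df.loc[sids, "site"]).to_numpy(float)[:, 1:],
        base_df.loc[sids, "motion"].to_numpy(float)])
    if len(sids) < 20:
        return None
    return nested_elasticnet_predict(
        features, iq, covariates, n_reps=config.prediction_reps,
        seed=derive_seed(config.seed, "predict"))
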