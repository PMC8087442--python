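# manecc — longitudinal connectome manifold analysis

`manecc` tracks how the organization of the structural connectome changes
across adolescence by embedding each subject's white-matter connectivity
matrix into a compact manifold space and following every region's position
over repeated visits. It is written for network-neuroscience researchers
running accelerated longitudinal designs (wide age range, short per-subject
follow-up) who want the full chain — group-template construction,
diffusion-map embedding, alignment, statistics, and outcome prediction — as
tested, scriptable building blocks, plus a synthetic cohort generator for
method validation when the underlying cohort data are access-restricted.

## The statistic at the core

A visit's connectome `W` (parcels × parcels streamline strengths) is
log-transformed and converted to a normalized-angle affinity
`A_ij = 1 − arccos(cos θ_ij)/π` between row profiles. Diffusion map
embedding of `A` (density normalization α = 0.5, diffusion time t = 0,
multiscale scaling λ/(1 − λ)) yields eigenvector coordinates E1..E3 per
parcel. Individuals are aligned to a template manifold (from a held-out,
demographically matched template cohort) by orthogonal Procrustes, and each
region i is summarized by its **manifold eccentricity**

    ME_i = sqrt( Σ_{e=1..3} (IE_e(i) − CT_e)² ),

the Euclidean distance from the template-manifold centroid CT. Expansion
(increasing ME) means a region's connectivity profile is differentiating
from the rest of the brain. Change across age is modeled per region with a
linear mixed-effects model

    ME ~ 1 + age + sex + site + motion + (1 | subject)

(REML, FDR q < 0.05), contextualized with graph measures (degree,
within-module degree, participation, connectivity distance), spatial
spin-permutation nulls, subcortical projections, and a nested elastic-net
prediction of follow-up IQ. `docs/methods.md` has the full model account.

## Worked example

```python
import numpy as np
from manecc import (CohortConfig, RunConfig, fit_lme_per_feature,
                    simulate_cohort, simulate_parcellation)
from manecc.pipeline import compute_manifold_features, designate_expanding_community

parcels = simulate_parcellation(n_cortical=200, n_subcortical=14, seed=11)
comm = designate_expanding_community(parcels, seed=11)  # the "transmodal" set
expanding = parcels.table.query("community == @comm").parcel_id.to_numpy()

cohort = CohortConfig(n_subjects=100, expanding_set=tuple(expanding), seed=11)
run = RunConfig(cohort=cohort, seed=11)
feats = compute_manifold_features(parcels, simulate_cohort(cohort), run)

res = fit_lme_per_feature(feats["eccentricity"], feats["visits_df"],
                          feature_ids=parcels.cortical_ids)
tab = res.table.set_index("feature_id")
in_set = np.isin(parcels.cortical_ids, expanding)
print(f"designated community: {comm} ({in_set.sum()} parcels)")
print(f"template variance explained: "
      f"{np.round(feats['template'].variance_explained * 100, 1)} %")
print(f"mean alignment r: {np.nanmean(feats['alignment']):.3f}")
print(f"significant expanding regions: "
      f"{int((tab.significant & (tab.t > 0))[in_set].sum())}/{in_set.sum()}")
print(f"mean age-t in expanding set: {tab.t[in_set].mean():.2f}, "
      f"elsewhere: {tab.t[~in_set].mean():.2f}")
```

prints

```
designated community: limbic (30 parcels)
template variance explained: [7.6 7.3 7.1] %
mean alignment r: 0.983
significant expanding regions: 30/30
mean age-t in expanding set: 8.97, elsewhere: -1.13
```

The first three eigenvectors carry the largest share of the affinity
spectrum; individuals align to the template almost perfectly on this clean
synthetic cohort; and the mixed model recovers the injected expansion in
all 30 designated parcels while the rest of the cortex stays flat.

There is also a CLI mirroring the stages
(`manecc simulate | template | embed | align | eccentricity | subcortical |
lme | graph | spin | predict | run`); `manecc run --seed 11 --out-dir out/`
executes the whole pipeline and writes per-stage TSVs plus a manifest with
hashes and the seed.

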