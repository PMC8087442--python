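# Methods

`manecc` implements a longitudinal analysis of structural-connectome
organization in low-dimensional manifold space, together with a synthetic
cohort generator that reproduces the statistical structure such an analysis
assumes. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## The analysis model

**Connectome manifolds.** Each visit's connectome is a symmetric nonnegative
parcel × parcel matrix of streamline cross-section strengths, log-transformed
(`w → ln(1 + w)`) to compress its heavy tail. Row connectivity profiles are
sparsified (the weakest 90 % of each row zeroed by default) and compared with
a normalized-angle kernel,

    a_ij = 1 − arccos(cos(w_i·, w_j·)) / π  ∈ [0, 1],

giving an affinity matrix. The diffusion map of this affinity uses
anisotropic density normalization `W = A / (d_i d_j)^α` with α = 0.5,
row-normalization to a Markov operator, and spectral decomposition via the
symmetric conjugate `D^{-1/2} W D^{-1/2}` for numerical stability. With
diffusion time t = 0 the coordinates use the multiscale scaling
λ/(1 − λ); for t > 0 they use λ^t. α = 0.5 and t = 0 are defaults because
they retain the global relations between data points rather than emphasizing
any single diffusion scale. The trivial constant eigenvector is dropped, and
each component's sign is fixed so its largest-magnitude entry is positive —
a determinism device only, since Procrustes alignment absorbs residual flips.

**Template and alignment.** A template manifold is computed from a
group-representative connectome of a held-out template cohort (matched on
age stratum, sex, and site; template subjects never enter individual-level
statistics). The group connectome uses distance-dependent consensus
thresholding: edges observed in at least one subject are pooled by
hemisphere relation (intra vs inter, because inter-hemispheric edges are
systematically longer), binned into equal-frequency great-circle-distance
bins (10 per pool), and each bin retains its average per-subject edge count,
ranked by across-subject occurrence. This preserves consistently observed
long-range edges that plain frequency thresholding would discard.
Consistency thresholding (drop the highest-CV fraction of edges from the
average) and simple averaging are available alternatives. Individual
manifolds are aligned to the template with orthogonal Procrustes (rotation /
reflection only — no scaling or translation, so within-subject geometry is
untouched).

**Manifold eccentricity.** The template center is the centroid of the first
three template eigenvectors; a region's eccentricity is the Euclidean
distance of its aligned coordinates from that center over those three
components (an all-eigenvector variant is available). The center is computed
once from the template and reused for every individual and visit, so
longitudinal change in eccentricity is change of the individual relative to
a fixed origin. Subcortical regions, which are not part of the cortical
embedding, are projected into it by weighting the cortical manifold with
each region's (normalized) subcortico-cortical streamline strengths and
averaging across components.

**Longitudinal model.** Per feature (region eccentricity, subcortical
projection, edge weight, or centrality):

    value ~ 1 + age + sex + site + motion + (1 | subject)

by restricted maximum likelihood, two-sided p on the age term,
Benjamini–Hochberg FDR at q < 0.05. Because the same design is fitted to
hundreds of features, the default engine is a profiled-REML solver
specialized to the random-intercept model: for a fixed variance ratio
λ = σ²_subject/σ²_residual the GLS solution is closed-form via the blocked
Woodbury identity, and the REML criterion is a 1-D minimization in log λ.
It reproduces statsmodels MixedLM (the `engine="statsmodels"` option and the
cross-check oracle in the test suite) to ~1e-6 in coefficients at roughly
1 ms per fit. Degrees of freedom for the age contrast use a
Satterthwaite-style approximation — finite-difference gradient of the
contrast variance against the numerically evaluated 2 × 2 REML information
in (σ²_e, σ²_b) — clamped to [1, n − p]; `df_method="residual"` and
`"normal"` are available, and the quadratic-age variant centers age before
squaring to avoid collinearity.

**Graph context.** Degree (weighted row sums), betweenness (Brandes on edge
lengths 1/w — the convention of the standard connectivity toolbox, rather
than −ln w), eigenvector centrality (per connected component),
connectivity distance (mean great-circle distance to connected nodes; a real
geodesic matrix can be injected), Louvain modules at γ = 1 (seeded restarts,
best modularity kept; 10 restarts in the per-subject pipeline loop, more via
parameter), and a k-means consensus over subjects' co-assignment matrices
with k chosen by silhouette (k ∈ 2..10, 50 k-means restarts). Within-module
degree is z-scored per module; participation is 1 − Σ(κ_is/k_i)². Clusters
of significant parcels are connected components on the parcel adjacency
graph. Change–change associations correlate within-subject Δeccentricity
with Δmetric per cluster, with permutation p-values (metric vector shuffled;
the choice of which vector to shuffle is immaterial under exchangeability)
and BH correction across clusters.

**Spatial null.** Spin tests rotate the parcel centroids with uniform SO(3)
rotations (mirrored across hemispheres) and reassign values by nearest
rotated centroid (duplication allowed — the simplest published variant);
p = (1 + #{|null r| ≥ |r|})/(n_rot + 1), two-sided.

**Prediction.** Follow-up IQ is predicted from baseline and change features
with nested 10-fold cross-validation: the inner loop tunes the elastic-net
penalty (mixing ratio 0.5; 20 log-spaced penalties from the data-driven
maximum down to 10⁻³ of it) by inner-fold MAE; the elastic net acts as a
feature selector, and a plain linear model on the selected features plus
covariates (age, sex, site, motion, entered as regressors — residualizing
the target is available by flag) makes the predictions. The whole procedure
repeats with reshuffled folds (100 by default; fewer in the bundled
experiments). A training-mean baseline and Meng's z-test for correlated
correlations quantify improvement; permutation p-values rerun the full
nested procedure on shuffled targets.

## The synthetic cohort

The generator emulates an accelerated longitudinal study: two visits per
subject ~0.5–1 y apart, baseline ages 14–25 y in five equal strata with
sexes balanced ±1 per stratum, three sites round-robin, half-normal head
motion (mean 0.15 mm), and a pubertal (Tanner) score for ~35 % of subjects
at baseline only, increasing noisily with age. The default cohort size is
208 subjects; the bundled experiments run 40–100 subjects.

Connectome edges follow a lognormal model on 200 cortical (two mirrored
hemispheres of quasi-uniform spherical centroids, seven contiguous
functional communities, four latitude-band hierarchy classes) plus 14
subcortical parcels:

    log w_ij = a0 − d_ij/λ_d + b·[same community] + c·(1 − |g_i − g_j|)
               + β_age (age − 20)·[i, j ∈ expanding set, same community]
               + site offset + subject intercept + ε,
    ε ~ N(0, (σ_noise (1 + motion))²)

with d the great-circle centroid distance (λ_d = 0.8 rad), g the centroid
z-coordinate (a smooth hemisphere-symmetric gradient that yields a dominant
embedding axis), and the weakest 65 % of edges pruned. Noise lives on
log-weights so weights stay nonnegative; the reference age 20 (mid-range)
decouples intercepts from slopes. Caudate- and thalamus-labeled
subcortico-cortical rows carry their own age coefficient, mirroring the
subcortical findings being emulated; which rows carry it is configurable.
IQ is a linear function of designated (standardized) manifold features plus
N(0, 10) noise with weights of 5 IQ points per SD — a moderate brain–behavior
coupling, deliberately stronger than typical empirical effect sizes so that
prediction experiments have signal at n = 100.

The subcortical age effect on caudate/thalamus rows strengthens their
connections to the *preferred community* rather than the whole row: the
manifold projection normalizes each region's weights, so a uniform row gain
would cancel exactly; a community-selective gain shifts the normalized
weight profile and hence the projected position, which is what
"reconfiguration of subcortico-cortical pathways" means in manifold terms.

**The injected effect size.** β_age defaults to 0.02/yr (2 %/yr within-
community strengthening, ×1.27 over the 12-year window). Pilot simulations
showed that much larger effects (5 %/yr) drive a global reconfiguration of
the embedding — compensatory contraction and spillover expansion well
outside the injected set — because eigenvector geometry is global; 2 %/yr
produces a subtle, fully detectable effect whose significant expansion is
confined to the injected set. Recovery experiments inject the effect into a
whole functional community (the generator strengthens within-community
edges, so a partial community leaks directly into its excluded half) and
score detection as FDR-significant *expansion* (positive age effect), the
directional alternative the design emulates. Not every community makes a
well-posed expansion experiment, for two reasons intrinsic to the
statistic. First, eccentricity measures distance from the template center:
a community sitting at the center cannot move away from it, so
strengthening it merely tightens it in place (undetectable). Second, the
embedding is global: a community with strong leverage on the eigenvectors
drags near-center parcels along, and because those parcels start at
near-zero eccentricity even small displacements register as significant
"expansion" (spillover false positives that are not spatial neighbors of
the injected set but occupants of the manifold origin). The designated
community is therefore chosen by a pilot-screening rule
(`pipeline.designate_expanding_community`): every candidate community of
roughly 30 parcels is screened with one small pilot cohort and the
community whose detected expansion is most confined to the injected set is
designated — the synthetic analogue of a power analysis, run on cohorts
independent of those later analyzed. This mirrors the scientific setting,
where the expanding regions are transmodal cortex away from the origin of
the principal gradients, and it makes explicit a genuine limitation of the
eccentricity statistic: effects injected at the manifold center are
invisible to it, and very strong effects anywhere contaminate the center.

## What the synthetic experiments do and do not show

The generator reproduces the features the statistics rely on: symmetric
nonnegative sparse connectomes with distance decay, community structure and
a smooth gradient; subject-level repeated measures with random intercepts;
site and motion nuisance; a ground-truth age effect. It does not reproduce
tractography biases (distance-dependent false negatives, gyral bias),
non-lognormal edge distributions, spatially autocorrelated noise beyond the
built-in smooth structure, dropout/attrition, or cognitive measurement
error. Passing tests therefore demonstrate correctness and calibration of
the machinery under the assumed data-generating process, not robustness to
real acquisition artifacts; the restricted study data's headline values are
not reproducible at desk scale and are not targets.

## Numerical choices and degenerate inputs

- Affinity rows that become all-zero after sparsification raise an error
  naming the parcel; disconnected affinity graphs are rejected.
- Degenerate eigenvalue pairs keep a stable order (sort by λ, then index);
  Procrustes handles rotation within pairs.
- Constant features, zero-variance moderators, and single-level categorical
  covariates yield absent statistics or a logged term drop, never silent
  zeros — avoiding spurious FDR dilution.
- PCA as an alternative decomposition is applied to the same
  normalized-angle affinity as the diffusion map, making the two directly
  comparable (first components agree to |r| > 0.999 on synthetic group
  connectomes); `pca_embed` also accepts a raw log-connectome.
- Every randomized stage derives its seed from the single global seed and
  the stage name, so full runs are bit-reproducible.

## Problem sizes in the bundled experiments

The test suite and `scripts/acceptance.py` run the study at reduced scale,
chosen as the smallest sizes at which each property is statistically
decidable: 20-node graphs for embedding-oracle equivalence; 100-parcel
group connectomes for decomposition consistency; 40-subject, 60-parcel null
cohorts (100 replicates) for mixed-model calibration; 100-subject,
200-parcel cohorts (20 replicates) for recovery of the injected expansion;
200 spin replicates at 200 rotations; and 100-subject prediction with 10
repetitions of the nested cross-validation.
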