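# Methods

This note documents the models, conventions and design choices behind
`lesionmorph`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The synthetic cohort model

The generator emulates the *structure* of a multi-cancer, lesion-level CT
cohort, not the physics of CT. No public cohort of this kind exists at the
required annotation granularity, so all distributional choices below are
stand-ins chosen for plausibility and analyzability — they are the study
conditions of every downstream experiment, fixed once.

**Geometry (lineage effect).** A lesion is an ellipsoid with minor diameter
("short axis") drawn uniformly from 10–16 mm — the 10 mm floor mirrors the
minimum size segmentation protocols use — and major/minor ratio drawn from
the tumor-type profile (defaults: means 1.25–1.60 across five types, SD
0.15, heavily overlapping). The surface is perturbed radially by a smooth
random field with amplitude 0.3–0.8 voxels. Orientation is uniformly
random. The lineage signal is weak *by construction*: the analysis is about
detecting that environment dominates, so the generator plants a shape effect
that is present but not cleanly separable.

**Appearance (environment imprint).** Inside the mask the image is
`mean + sd · G_sigma` where `G_sigma` is Gaussian-filtered white noise
rescaled to unit marginal SD (`sigma` = texture correlation length in
voxels), plus an optional rim offset on the one-voxel boundary layer, plus
independent voxel noise (SD 10 HU) everywhere. Background is 0 HU plus
noise. Defaults plant four environments with portal-venous-plausible means
30 / 75 / 120 / 250 HU at common SD 15 HU — adjacent means separated by
three pooled SDs — and correlation lengths 0.6 / 1.0 / 1.6 / 2.2 voxels,
rims 0 / 15 / 25 / 0 HU.

**Cohort structure.** 200 patients × 3 lesions = 600 lesions by default.
Each patient carries one tumor type; lesion classes follow the mixture 10%
primary / 25% lymph-node / 65% solid-organ metastases (close to the class
balance of large clinical cohorts). Primaries live in their type's home
organ, so type and environment coincide for them; solid-organ metastases
draw their environment uniformly (independently of type, making the null
behavior of lineage concordance analyzable; an affinity matrix is available
but defaults to uniform); nodal metastases go to a `lymph_node` environment
when one is configured, else draw uniformly. At most ten lesions per
(patient, organ) are placed. One lesion per 64³ volume at 1 mm spacing
(anisotropic spacing configurable to exercise resampling).

**Determinism.** The cohort is a pure function of the config including its
seed; each lesion's volume uses a child generator keyed by (seed, lesion
index), so individual lesions are reproducible in isolation.

**What the generator does not emulate** — and what passing tests therefore
do not show about clinical data: whole-body anatomical context, scanner and
protocol batch effects, contrast kinetics, partial-volume and motion
artifacts, reader variability in segmentation, and any correlation between
lesion size/shape and environment. Recovery of the planted imprint
demonstrates that the *pipeline* measures what it claims to measure, not
that real tumors behave this way.

## 2. Feature extraction

Arrays are indexed (slice, row, col); physical coordinates are
`index × spacing`; NRRD `space directions` is the source of truth for
spacing. All operators are mask-relative, so features are invariant under
whole-voxel translations, and shape features under intensity rescaling.

* **Resampling:** to 1 mm³ isotropic (cubic B-spline for the image;
  nearest-neighbour + re-binarization at 0.5 for the mask — interpolating a
  binary mask with splines would manufacture gray levels).
* **Discretization:** fixed bin width 25 HU by default
  (`level = floor((v − min)/w) + 1`); fixed bin count available.
* **Shape (14):** voxel-count volume; exposed-voxel-face surface area (an
  exactly testable simplification of mesh-based area — it overestimates
  smooth surfaces and is documented as such); surface/volume; sphericity;
  compactness; maximum 3-D diameter (largest pairwise distance between
  surface voxel centers, convex-hull pruned); PCA axis lengths `4√λ`;
  elongation and flatness as eigenvalue ratios (`= 1` for a single voxel by
  convention); 2-D area, perimeter and diameter on the largest-area axial
  slice.
* **First order (14):** mean, median, min, max, range, population variance,
  skewness, Pearson kurtosis, energy, entropy in bits on discretized
  levels, 10th/90th percentiles, IQR, robust mean absolute deviation
  (within the 10–90 percentile band).
* **Texture (37):** GLCM (13 unique 3-D offsets, symmetric, features
  averaged over offsets), GLRLM (13 directions, averaged), GLSZM
  (26-connected zones), NGTDM (26-neighbourhood means), GLDM (dependence
  tolerance α = 0). Probability matrices normalize to 1; degenerate inputs
  (single gray level, single voxel) use fixed conventions (correlation → 0)
  rather than erroring, and genuinely undefined values propagate as NaN
  into downstream imputation.

The full bank is 65 features. This is a deliberately reduced, class-tagged
analogue of a production radiomics bank: the concordance analysis consumes
class tags and relative information content, not any specific feature, and
filtered-image (wavelet/LoG) derivatives are out of scope.

**Erosion.** The tumor-core arm erodes each mask once with the 3-D
6-connected (face-neighbour) element, out-of-grid counting as background. If
erosion disconnects the mask the largest 26-connected component is kept
(preserving connectivity); if it empties the mask the lesion is dropped
from the eroded analysis with a warning and listed in the report.

## 3. Embedding, clustering, optimization

Standardization z-scores each feature after median imputation; all-missing
and zero-variance columns are dropped with a warning. The 2-D map is
scikit-learn t-SNE (perplexity 30, 1000 iterations, PCA initialization,
seeded); these defaults are config-exposed since no canonical values exist
for cohorts of this kind. The embedding is treated as a *contract* —
deterministic under a fixed seed, locality-preserving for separated
structure — and tested as such, not re-implemented.

Clustering is hierarchical agglomeration (scipy linkage/fcluster) cut at k
clusters; ward requires the Euclidean metric; distance ties break by the
backend's deterministic merge order, which matters only on exactly tied
inputs.

Hyperparameters (k ∈ [2, 15]; linkage ∈ {ward, complete, average}) are
selected by maximizing `0.5·silhouette + 0.5·ARI(gt)` with a Gaussian
process (Matern 5/2) + expected improvement over the discrete space, seeded;
when the budget (default 50) covers the space this reduces to exhaustive
enumeration. The ARI term defaults to the **mean** of ARI against both
ground truths: the sources of this design do not say which labeling enters
model selection, and the symmetric choice avoids baking the conclusion
(environment dominance) into the selection step. `ari_mode` can pin it to
either labeling instead. A raw-feature variant applies the same optimizer
directly to the standardized feature matrix.

## 4. Concordance inference

ARI follows the Hubert–Arabie form with the convention that a vanishing
normalizer (both partitions trivial) yields 0. Silhouette is the Rousseeuw
mean width with s = 0 for singleton clusters, Euclidean distances.

The bootstrap is **paired**: each of the B = 100 replicates draws n lesion
indices with replacement and recomputes both ARIs on that same draw, so the
difference is a paired comparison (strictly more powerful than independent
draws, and the natural reading of "difference in ARI"). Whether to pair, and
whether to re-cluster per replicate, are genuinely open choices; both are
surfaced in the API (`refit_per_replicate` re-clusters each resample on the
fixed representation at the selected hyperparameters) and
the default — fixed partition, paired draws — reflects that re-embedding
and re-optimizing 100× is neither computationally plausible at cohort scale
nor standard. CIs are 95% percentile intervals. The p-value uses the
add-one rule `(1 + #{diff ≤ 0})/(B + 1)`, bounded below by 1/101 — which is
why headline results report `p < 0.010` rather than zero.

**A known statistical property:** under *exact* independence of labeling
and partition, ARI is a degenerate U-statistic (its first-order projection
vanishes), and the nonparametric bootstrap overestimates the variance of
degenerate U-statistics. The one-sided test is therefore conservative at
the null — its empirical rejection rate at nominal 5% sits around 1% —
while retaining full power against the planted alternatives. The unit suite
asserts validity (the rate never exceeds the nominal band); an exactly
nominal type-I rate is not attainable with this estimator and is not
claimed.

Contingency tables are row-normalized: each ground-truth class is
distributed across clusters, rows summing to 100%.

## 5. Experiments and reproducibility

Each grid cell (lesion subset × feature class × mask variant ×
representation) re-runs standardization, embedding and optimization on its
own subset — per-subset cluster counts and silhouettes are part of the
output, so reusing the full-cohort clustering would be wrong. Environment
labels can be coarsened by a user-supplied grouping map (identity by
default), since grouping of anatomical sites is cohort-specific.

Every stage has its own named seed (cohort, embedding, optimizer,
bootstrap). Persisted artifacts (feature/embedding/partition CSVs,
concordance JSON, contingency tables, report) carry a provenance stamp of
config hash, seeds and package version — deliberately no timestamp, so a
repeated run is byte-identical. Failed grid cells are marked and skipped
without aborting the grid.

**Problem sizes.** The acceptance-level planted-structure checks run ten
600-lesion cohorts through the full embedding pipeline, plus ablation and
erosion arms on one cohort. Unit-level property checks (null control with
the imprint disabled, the separability dial from zero to full spread) run
on 75–120-lesion cohorts with the raw-feature representation and reduced
search budgets — these sizes were chosen as the smallest at which the
properties are stable, and they are part of the package's test design, not
tunable tolerances.

## 6. Known limitations

* Feature values are not feature-for-feature comparable with any specific
  production radiomics implementation (reduced bank, face-counting surface
  area, averaged-matrix conventions).
* The optimizer's GP path is only exercised when the budget is below the
  space size; the default configuration enumerates the space exactly.
* The eroded arm drops degenerate lesions rather than imputing them, so
  eroded and full analyses can run on slightly different lesion sets.
* ARI comparisons across cohorts of different size/class balance are not
  calibrated against each other; only within-cohort contrasts are
  interpreted.
* The paired bootstrap p-value is conservative near the exact-independence
  null (see §4).
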