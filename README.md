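# lesionmorph

**Does a tumor's CT appearance follow its lineage, or the organ it grows in?**

`lesionmorph` is a lesion-level CT radiomics pipeline for quantifying how
strongly unsupervised *morphological clusters* of lesions align with two
competing biological labelings:

* **tumor type** — the site of the primary tumor (lineage), and
* **anatomical environment** — the organ/system the individual lesion
  resides in.

It is aimed at radiomics and imaging-AI researchers who want to measure (or
stress-test) the "environmental imprint" effect: when disparate cancers grow
in the same organ their imaging phenotypes converge, which confounds any
model that tries to read tumor lineage off morphology alone.

Because clinical multi-cancer cohorts of this kind are not publicly
shareable, the package ships a first-class **synthetic cohort generator**
that plants the effect with known ground truth: each lesion is a perturbed
ellipsoid whose in-mask intensity/texture is a property of its environment
(mean HU, marginal SD, texture correlation length, optional rim) and whose
geometry (axis ratio, surface roughness) is a deliberately weak property of
its tumor type.

## The analysis

For each lesion, a class-tagged radiomic feature vector is extracted
(IBSI-style): 14 shape features from the mask, 14 first-order intensity
statistics, and 37 texture features from the GLCM, GLRLM, GLSZM, NGTDM and
GLDM gray-level matrix families, after resampling to 1 mm³ isotropic voxels
(cubic B-spline for images, nearest-neighbour for masks) and fixed-bin-width
discretization (25 HU).

Features are median-imputed and z-scored, embedded into 2-D with t-SNE, and
clustered by agglomerative clustering whose hyperparameters (k, linkage) are
chosen by Bayesian optimization of the equal-weight objective

```
objective = 0.5 · silhouette(points, C) + 0.5 · ARI(C, ground truth)
```

Concordance uses the Hubert–Arabie adjusted Rand index

```
ARI = (Index − E[Index]) / (Max − E[Index]),   Index = Σ_ij C(n_ij, 2)
```

computed between the cluster partition C and each labeling. Inference is a
**paired lesion bootstrap**: B = 100 resamples of lesions with replacement,
each recomputing ARI_type and ARI_env on the same draw; reported are means,
95% percentile CIs, the mean difference, and the one-sided add-one p-value
`p = (1 + #{ARI_env,b − ARI_type,b ≤ 0}) / (B + 1)` for H1 "environment
concordance exceeds lineage concordance".

The experiment grid mirrors the clinical study design: lesion-class strata
(all / metastatic / solid-organ metastases), feature-class ablation
(shape / intensity / texture only), a raw-feature-vector variant that skips
the embedding, and a tumor-core robustness arm that erodes every mask by one
voxel with a 3-D 6-connected structuring element before extraction.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_concordance_bootstrap.py` (150 synthetic lesions,
solid-organ subset, raw-feature representation) prints:

```
solid-organ metastases analysed: n=99, k=4
mean ARI (tumor type):   0.041  95% CI [-0.001, 0.109]
mean ARI (environment):  0.641  95% CI [0.527, 0.750]
mean difference:         0.599  95% CI [0.463, 0.719]
one-sided p-value:       0.0099  (minimum attainable: 0.0099)
```

Reading: the four discovered morphological clusters agree strongly with the
organ environment (mean ARI 0.64) and not with tumor lineage (0.04); the
difference is positive on every one of the 100 bootstrap draws, so the
p-value sits at its floor 1/101. The accompanying contingency table shows
each environment concentrating in one cluster.

The same pattern at full scale, via the CLI:

```bash
lesionmorph simulate --seed 0 --out scratch/cohort/
lesionmorph extract --in scratch/cohort/ --out scratch/features.csv
```

## Layout

```
src/lesionmorph/
  cohort.py        synthetic lesion cohorts (the planted imprint)
  features.py      resampling, discretization, shape/first-order, erosion
  texture.py       GLCM / GLRLM / GLSZM / NGTDM / GLDM
  embedding.py     standardization, t-SNE, agglomerative clustering
  optimize.py      GP + expected-improvement hyperparameter search
  stats.py         ARI, silhouette, paired bootstrap, contingency tables
  experiments.py   the experiment grid and its reports
  io.py, cli.py    NRRD/CSV/YAML formats and the `lesionmorph` command
docs/methods.md    model assumptions, parameter choices, limitations
examples/          one narrative script per capability
```
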