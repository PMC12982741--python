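"""Extract class-tagged radiomic features from synthetic lesions.

The extractor resamples to 1 mm isotropic voxels, computes 14 shape
features from the mask, first-order intensity statistics, and texture
features from five gray-level matrix families (GLCM, GLRLM, GLSZM, NGTDM,
GLDM) on 25-HU-bin discretized levels.
"""

import lesionmorph as lm

config = lm.default_cohort_config(seed=0, n_patients=10)  # 30 lesions
pairs, table = lm.generate_cohort(config)
features, dropped = lm.extract_table(pairs, list(table["lesion_id"]))

print(f"extracted {len(features.metas)} features for {len(features.lesion_ids)} lesions")
by_class = features.meta_frame().groupby("feature_class").size()
print(f"per class: {by_class.to_dict()}\n")

frame = features.to_frame()
show = ["shape_volume", "firstorder_mean", "firstorder_entropy", "glcm_contrast"]
merged = table.set_index("lesion_id").join(frame[show])
print(merged.groupby("environment")[show].mean().round(2).to_string())
print(
    "\n-> mean intensity separates the environments cleanly (the planted imprint);"
    "\n   shape_volume varies with lesion size, not environment."
)
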