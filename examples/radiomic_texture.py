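"""Extract the 66-metric texture panel from synthetic bone-lesion ROIs.

20 first-order intensity metrics over masked pixels plus 46 GLCM metrics (23
Haralick-style statistics summarized across 4 directions at distance 1).
"""

import liqrad as lq
from liqrad import radiomics

cohort = lq.generate_cohort(lq.CohortConfig(n_patients=4, seed=5))
rois = lq.generate_roi_images(cohort, lq.TextureSpec(seed=6))
print(f"{len(rois)} ROIs (5 lesions x {len(cohort)} patients)")

panel = radiomics.extract_cohort_panel(rois)
manifest = radiomics.panel_manifest()
print(f"panel: {len(manifest['intensity'])} intensity + {len(manifest['glcm'])} "
      f"GLCM = {panel.shape[1] - 2} metrics per ROI")

row = panel.iloc[0]
print(f"example ROI {row['patient_id']}/{row['lesion_id']}:")
for k in ("intensity_entropy", "intensity_interquartile_range",
          "glcm_contrast_mean", "glcm_entropy_mean", "glcm_variance_mean",
          "glcm_energy_mean"):
    print(f"  {k:35s} {row[k]:.4f}")
# Higher GLCM entropy / variance = more spatially heterogeneous grey levels,
# the texture phenotype that tracks the cohort's latent disease factor.
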