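"""Generate a synthetic liquid-biopsy cohort and inspect its marginals.

A 22-patient cohort with zero-inflated overdispersed CTC counts (two
platform views thinned from one true count), log-normal plasma cfDNA, and a
shared latent heterogeneity factor coupling them.
"""

import numpy as np

import liqrad as lq

cohort = lq.generate_cohort(lq.CohortConfig(n_patients=22, seed=7))

detected = (cohort["rarecyte_count"] > 0).sum()
pos = cohort.loc[cohort["rarecyte_count"] > 0, "rarecyte_count"]
print(f"patients: {len(cohort)}, with detectable CTCs: {detected}")
print(f"CTC counts among positives: median {pos.median():.1f}, "
      f"range {pos.min()}-{pos.max()}, total {int(pos.sum())}")
print(f"cfDNA ng/mL: mean {cohort['cfdna_ng_ml'].mean():.1f}, "
      f"range {cohort['cfdna_ng_ml'].min():.1f}-{cohort['cfdna_ng_ml'].max():.1f}")
print(f"platform concordance R^2: {lq.platform_concordance(cohort):.3f}")
print(f"corr(latent, log cfDNA): "
      f"{np.corrcoef(cohort['latent'], np.log(cohort['cfdna_ng_ml']))[0,1]:.2f}")
# The latent factor is the knob that later makes cluster prevalence and
# lesion texture co-vary with CTC burden and cfDNA level.
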