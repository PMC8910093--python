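"""Unpack opaque K-means clusters into CART threshold rules.

One-vs-rest Gini trees with cost-complexity pruning chosen by 10-fold CV
deviance; a cluster's tree is only treated as an interpretation when both CV
sensitivity and specificity exceed 80%.
"""

import numpy as np
import pandas as pd

import liqrad as lq
from liqrad.containers import FeatureMatrix

rng = np.random.default_rng(0)
n = 150
# cluster 1 = "large nucleus" cells, defined by one morphometric threshold
nuclear_area = np.concatenate([rng.uniform(40, 90, n), rng.uniform(120, 200, n)])
data = pd.DataFrame(
    {
        "nuclear_area": nuclear_area,
        "ck_texture": rng.normal(size=2 * n),
        "cell_roundness": rng.normal(size=2 * n),
    }
)
labels = pd.Series((nuclear_area > 100).astype(int), index=data.index)
matrix = FeatureMatrix(
    data=data,
    categories={c: "morphology" for c in data.columns},
    patient_ids=pd.Series(["p"] * (2 * n), index=data.index),
)

report = lq.unpack_cluster(matrix, labels, cluster_id=1, seed=1)
print(f"CV sensitivity {report.sensitivity:.2f}, specificity {report.specificity:.2f}")
print(f"passes >80%/>80% gate: {lq.gate_unpacking(report)}")
print("rules:")
for rule in report.rules:
    print("  ", rule)
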