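"""Run the whole chain on a reduced synthetic study and print the report.

simulate -> phenotype -> cluster (both approaches) -> unpack -> variant/CN
QC -> radiomics -> associate; every artifact lands in ./pipeline_out.
The default (study-scale) configuration is `lq.run_pipeline(seed, outdir)`;
this example shrinks the feature panel and iteration counts to finish in
about a minute.
"""

import json

import liqrad as lq

cfg = lq.PipelineConfig(
    n_features=60, n_informative=6, iterations_a=10, iterations_b=10,
    candidates_a=10, candidates_b=10, k_range=(2, 6),
)
result = lq.run_pipeline(seed=17, outdir="pipeline_out", config=cfg)

print(json.dumps(result.metrics, indent=2))
print("artifacts:", sorted(p.name for p in result.outdir.iterdir()))
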