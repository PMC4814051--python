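"""Run the full pipeline (simulate -> modules -> GSA -> concordance ->
self-ID -> variance decomposition -> report) and show the summary."""

import json

import txconcord as tx

config = tx.RunConfig(
    sim=tx.SimulationConfig(n_genes=400, n_modules=10, module_size_range=(8, 16),
                            n_drugs=20, experiments_per_drug=5, seed=5),
    n_per_bin=300, n_aligned_sets=8, n_random_sets=16,
)
summary = tx.run_pipeline(config, "pipeline_output")
print(json.dumps(summary, indent=1, default=float))
print("per-stage TSV artifacts written under pipeline_output/")
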