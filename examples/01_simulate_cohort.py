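"""Simulate a toxicogenomics training cohort with planted co-expression
structure and print what was generated."""

import txconcord as tx

config = tx.SimulationConfig(n_genes=800, n_modules=16, n_drugs=30,
                             experiments_per_drug=5, seed=0)
logfc, meta, truth = tx.generate_training_cohort(config)

print(f"logFC matrix: {logfc.frame.shape[0]} genes x {logfc.frame.shape[1]} experiments")
print(f"drugs: {meta['compound'].nunique()}, dose grid {config.doses}, "
      f"time grid {config.times_h} h")
n_module_genes = sum(len(g) for g in truth.module_genes.values())
print(f"planted modules: {len(truth.module_genes)} covering {n_module_genes} genes")
print(f"per-experiment common-axis activity: "
      f"median {truth.common_activity.median():.3f}, "
      f"max {truth.common_activity.max():.3f}")
# The latent table records, for every module and experiment, the activity the
# generator actually injected -- the ground truth later stages try to recover.
print(f"fraction of (module, experiment) latents exactly quiescent: "
      f"{(truth.latent == 0).to_numpy().mean():.2f}")
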