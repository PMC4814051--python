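"""Derive co-expression modules from a simulated cohort, merge redundant ones,
and score an experiment with the scale-not-center eigengene scheme."""

import pandas as pd

import txconcord as tx

config = tx.SimulationConfig(n_genes=800, n_modules=16, n_drugs=30,
                             experiments_per_drug=5, seed=0)
logfc, meta, truth = tx.generate_training_cohort(config)

models = tx.build_module_models(logfc)
n_base = sum(m.is_base for m in models)
print(f"derived {sum(m.kind == 'unmerged' for m in models)} modules; "
      f"{sum(m.kind == 'merged' for m in models)} merged groups; {n_base} base modules")

scores = tx.training_scores(models, logfc)
print(f"training score sd per module (must be 1 by construction): "
      f"{scores.std(axis=1, ddof=1).round(6).unique()}")

activity = tx.avg_abs_eg(scores, models)
eid = activity.idxmax()
print(f"most perturbing experiment: {eid} with avg. abs. EG = {activity[eid]:.2f}")
print("its strongest module scores (units: training standard deviations):")
print(scores[eid].abs().sort_values(ascending=False).head(3).round(2).to_string())

# scoring never centers: a profile with no fold changes scores exactly zero
zero = pd.Series(0.0, index=logfc.genes)
print(f"all-zero profile scores: "
      f"{[tx.score_experiment(zero, m).score for m in models[:3]]} ...")
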