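"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator plants the features the concordance framework measures:

* disjoint co-expression modules with first-PC-like gene loadings;
* sparse, heavy-tailed per-experiment module activities (most modules are
  quiescent in any one experiment, as for a toxicology training cohort);
* same-drug experiments whose latent activities correlate
  rho = exp(-time_decay * |log10 t1/t2| - dose_decay * |log10 d1/d2|),
  so concordance decays strongly with time difference and weakly with dose;
* a shared stress-response axis whose contribution grows with an experiment's
  overall activity, which raises random different-drug pair similarity at
  high transcriptional activity;
* a second system in which the shared latent signal is attenuated and a fixed
  culture-vs-tissue baseline-shift profile is added to every experiment.

Model: logFC[g, e] = sum_m W[g, m] s[m, e] + caw * c[g] * a[e] + eps,
with W nonzero only for module members, a[e] the mean |s[., e]|, and
eps ~ Normal(0, noise_sd). Everything is deterministic under a fixed seed;
each stochastic step consumes a named substream of the global seed.

A calibration mode (``fixed_same_drug_rho``) replaces the decay model with a
constant equicorrelation and draws dense homogeneous latents, so that rho = 0
makes same-drug pairs genuinely exchangeable with random different-drug pairs
(the null-calibration setting) and rho > 0 plants a tunable signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from ._rng import substream
from .concordance import enumerate_same_drug_pairs
from .data import GeneSet, GeneSetCollection, LogFCMatrix, meta_frame, ExperimentMeta

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_modules: int = 40
    module_size_range: tuple = (10, 30)
    n_drugs: int = 60
    experiments_per_drug: int = 5
    doses: tuple = (10.0, 30.0, 100.0)          # mg/kg-like grid
    times_h: tuple = (3.0, 6.0, 9.0, 24.0, 96.0, 192.0)
    loading_scale: float = 1.0
    activity_scale: float = 1.0                  # per-drug latent magnitude
    module_active_prob: float = 0.3              # fraction of modules responding per drug
    common_axis_weight: float = 0.15             # shared stress-response strength
    noise_sd: float = 0.3
    time_decay: float = 1.0                      # per |log10 time ratio|
    dose_decay: float = 0.02                     # per |log10 dose ratio|, small
    fixed_same_drug_rho: float | None = None     # calibration mode override
    cross_system_attenuation: float = 0.5
    baseline_shift_magnitude: float = 2.5        # in training-sd (module score) units
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.module_size_range
        if lo < 5:
            raise ValueError("module sizes must be >= 5")
        if self.n_modules * hi > self.n_genes:
            raise ValueError("module sizes exceed the number of genes")
        for name in ("loading_scale", "activity_scale", "common_axis_weight",
                     "noise_sd", "time_decay", "dose_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.cross_system_attenuation <= 1.0:
            raise ValueError("cross_system_attenuation must be in [0, 1]")
        if self.fixed_same_drug_rho is not None and not 0.0 <= self.fixed_same_drug_rho < 1.0:
            raise ValueError("fixed_same_drug_rho must be in [0, 1)")
        n_grid = len(self.doses) * len(self.times_h)
        if self.experiments_per_drug > n_grid:
            raise ValueError("experiments_per_drug exceeds the dose x time grid")


@dataclass
class GroundTruth:
    """Planted structure recorded for every generated experiment."""

    module_genes: dict                 # module name -> list of gene ids
    loadings: pd.DataFrame             # genes x modules, zero off-module
    latent: pd.DataFrame               # modules x experiments (s)
    common_axis: pd.Series             # per-gene c
    common_activity: pd.Series         # per-experiment a
    meta: pd.DataFrame
    config: SimulationConfig

    def planted_rho(self, experiment_a: str, experiment_b: str) -> float:
        """Planted latent correlation for a same-drug pair (0 across drugs)."""
        meta = self.meta.set_index("experiment_id")
        a, b = meta.loc[experiment_a], meta.loc[experiment_b]
        if a["compound"] != b["compound"]:
            return 0.0
        cfg = self.config
        if cfg.fixed_same_drug_rho is not None:
            return float(cfg.fixed_same_drug_rho)
        dt = abs(np.log10(a["time_h"] / b["time_h"]))
        dd = abs(np.log10(a["dose"] / b["dose"]))
        return float(np.exp(-cfg.time_decay * dt - cfg.dose_decay * dd))


def _plant_structure(config: SimulationConfig):
    rng = substream(config.seed, "structure")
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    member_idx = rng.choice(config.n_genes, size=int(sizes.sum()), replace=False)
    module_genes, loadings = {}, np.zeros((config.n_genes, config.n_modules))
    offset = 0
    for m, size in enumerate(sizes):
        idx = member_idx[offset:offset + size]
        offset += size
        name = f"PM{m + 1:03d}"
        module_genes[name] = sorted(genes[i] for i in idx)
        mags = config.loading_scale * np.abs(rng.normal(1.0, 0.25, size=size))
        signs = np.where(rng.random(size) < 0.7, 1.0, -1.0)  # mix induced/repressed
        loadings[idx, m] = mags * signs
    W = pd.DataFrame(loadings, index=genes, columns=list(module_genes))
    c = pd.Series(rng.normal(0.0, 1.0, size=config.n_genes), index=genes, name="common_axis")
    return genes, module_genes, W, c


def _drug_conditions(config: SimulationConfig):
    rng = substream(config.seed, "meta")
    grid = [(d, t) for d in config.doses for t in config.times_h]
    out = []
    for k in range(config.n_drugs):
        drug = f"D{k + 1:03d}"
        chosen = rng.choice(len(grid), size=config.experiments_per_drug, replace=False)
        out.append((drug, [grid[i] for i in sorted(chosen)]))
    return out


def _same_drug_corr(config: SimulationConfig, conditions) -> np.ndarray:
    k = len(conditions)
    if config.fixed_same_drug_rho is not None:
        rho = config.fixed_same_drug_rho
        return (1 - rho) * np.eye(k) + rho * np.ones((k, k))
    log_d = np.log10([d for d, _ in conditions])
    log_t = np.log10([t for _, t in conditions])
    C = np.exp(-config.time_decay * np.abs(np.subtract.outer(log_t, log_t))
               - config.dose_decay * np.abs(np.subtract.outer(log_d, log_d)))
    return C


def _draw_latents(config: SimulationConfig, drugs, rng: np.random.Generator):
    """Latent module activities s (modules x experiments), experiment order
    following the drug/condition listing."""
    calibration = config.fixed_same_drug_rho is not None
    blocks = []
    for drug, conditions in drugs:
        k = len(conditions)
        C = _same_drug_corr(config, conditions)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(k))
        G = rng.standard_normal((config.n_modules, k)) @ L.T
        if calibration:
            s = config.activity_scale * G  # dense homogeneous latents
        else:
            gate = (rng.random(config.n_modules) < config.module_active_prob).astype(float)
            scale = rng.exponential(config.activity_scale, size=config.n_modules)
            s = (gate * scale)[:, None] * G
        blocks.append(s)
    return np.concatenate(blocks, axis=1)


def generate_training_cohort(config: SimulationConfig):
    """Simulate the training cohort; returns (LogFCMatrix, meta, GroundTruth)."""
    config.validate()
    genes, module_genes, W, c = _plant_structure(config)
    drugs = _drug_conditions(config)
    records, exp_ids = [], []
    for drug, conditions in drugs:
        for d, t in conditions:
            eid = f"{drug}_d{d:g}_t{t:g}"
            exp_ids.append(eid)
            records.append(ExperimentMeta(
                experiment_id=eid, compound=drug, dose=d, time_h=t,
                schedule="single" if t <= 24 else "repeat",
                system="rat_liver", source="synthetic",
            ))
    meta = meta_frame(records)
    S = _draw_latents(config, drugs, substream(config.seed, "latent"))
    a = np.abs(S).mean(axis=0)
    noise = substream(config.seed, "noise").normal(0.0, config.noise_sd,
                                                   size=(config.n_genes, len(exp_ids)))
    X = W.to_numpy() @ S + config.common_axis_weight * np.outer(c.to_numpy(), a) + noise
    logfc = LogFCMatrix(pd.DataFrame(X, index=genes, columns=exp_ids))
    truth = GroundTruth(
        module_genes=module_genes, loadings=W,
        latent=pd.DataFrame(S, index=list(module_genes), columns=exp_ids),
        common_axis=c, common_activity=pd.Series(a, index=exp_ids, name="common_activity"),
        meta=meta, config=config,
    )
    return logfc, meta, truth


def generate_same_drug_pairs(config: SimulationConfig, meta: pd.DataFrame,
                             truth: GroundTruth) -> pd.DataFrame:
    """All same-drug experiment pairs with covariates and planted latent
    correlation."""
    pairs = enumerate_same_drug_pairs(meta)
    if config.fixed_same_drug_rho is not None:
        pairs["planted_rho"] = config.fixed_same_drug_rho
    else:
        pairs["planted_rho"] = np.exp(
            -config.time_decay * pairs["log10_time_ratio"].to_numpy()
            - config.dose_decay * pairs["log10_dose_ratio"].to_numpy()
        )
    return pairs


def generate_cross_system_cohort(config: SimulationConfig, truth: GroundTruth,
                                 system: str = "RPH"):
    """A second-system cohort sharing the training cohort's drugs/conditions.

    Shared latent activities are multiplied by ``cross_system_attenuation``, a
    fixed baseline-shift profile (the culture-vs-tissue perturbation) is added
    to every experiment, and measurement noise is redrawn independently.
    """
    config.validate()
    rng = substream(config.seed, "cross_system")
    W = truth.loadings
    S2 = config.cross_system_attenuation * truth.latent.to_numpy()
    a2 = np.abs(S2).mean(axis=0)
    n_genes, n_exp = W.shape[0], S2.shape[1]
    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_exp))

    # baseline shift lives in module space so its avg. abs. EG is controlled:
    # per-module displacement ~ +/- baseline_shift_magnitude x the typical
    # training latent scale, projected through the planted loadings.
    train_latent_sd = truth.latent.to_numpy().std(axis=1, ddof=1)
    signs = np.where(rng.random(W.shape[1]) < 0.5, 1.0, -1.0)
    u = config.baseline_shift_magnitude * signs * np.abs(rng.normal(1.0, 0.3, size=W.shape[1]))
    shift = W.to_numpy() @ (u * train_latent_sd)

    X2 = W.to_numpy() @ S2 + config.common_axis_weight * np.outer(
        truth.common_axis.to_numpy(), a2) + shift[:, None] + noise

    meta2 = truth.meta.copy()
    meta2["experiment_id"] = meta2["experiment_id"] + f"_{system}"
    meta2["system"] = system
    logfc2 = LogFCMatrix(pd.DataFrame(X2, index=W.index, columns=meta2["experiment_id"]))
    shift_profile = pd.Series(shift, index=W.index, name="baseline_shift")
    return logfc2, meta2, shift_profile


def generate_gene_sets(truth: GroundTruth, n_aligned: int, n_random: int,
                       set_size: int = 15, aligned_frac: float = 0.7,
                       seed: int | None = None) -> GeneSetCollection:
    """Gene-set fixtures: aligned sets draw >= ``aligned_frac`` of members
    from one planted module, random sets draw uniformly from all genes."""
    if n_aligned + n_random == 0:
        raise ValueError("requested an empty gene set collection")
    if n_aligned > 0 and not truth.module_genes:
        raise ValueError("no planted modules to align gene sets to")
    rng = substream(truth.config.seed if seed is None else seed, "genesets")
    all_genes = list(truth.loadings.index)
    module_names = list(truth.module_genes)
    sets = []
    for i in range(n_aligned):
        mod = module_names[i % len(module_names)]
        members = truth.module_genes[mod]
        n_in = max(3, min(len(members), int(np.ceil(aligned_frac * set_size))))
        core = list(rng.choice(members, size=min(n_in, len(members)), replace=False))
        pool = [g for g in all_genes if g not in core]
        extra = list(rng.choice(pool, size=max(0, set_size - len(core)), replace=False))
        sets.append(GeneSet(name=f"aligned_{mod}_{i:03d}", members=tuple(core + extra),
                            category="custom", description=f"aligned to {mod}"))
    for i in range(n_random):
        members = rng.choice(all_genes, size=set_size, replace=False)
        sets.append(GeneSet(name=f"random_{i:03d}", members=tuple(members),
                            category="custom", description="uniform draw"))
    return GeneSetCollection(sets)
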