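"""End-to-end orchestration: simulate -> features -> concordance -> self-ID
-> variance decomposition -> report.

Every stage writes its TSV artifacts under the output directory, logs a
stage timer to standard error, and draws any randomness from named substreams
of the single configured seed, so a rerun with the same config is
reproducible. A stage failure aborts the run naming the stage; artifacts of
completed stages are retained.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import network
from ._rng import substream
from .concordance import LEVELS, best_match, pair_concordance
from .data import LogFCMatrix
from .gsa import page_zscore_matrix
from .io import write_gmt, write_logfc, write_meta
from .nullmodel import NullTable, build_null, self_id_probability, self_id_success
from .simulate import (
    SimulationConfig,
    generate_cross_system_cohort,
    generate_gene_sets,
    generate_same_drug_pairs,
    generate_training_cohort,
)
from .vardecomp import stepwise_fit

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    frac: float = 0.05
    n_per_bin: int = 1000
    n_aligned_sets: int = 20
    n_random_sets: int = 40
    cross_system: str = "RPH"
    metrics: tuple = ("pearson", "overlap")
    make_figures: bool = False

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload.pop("sim", {}).items()
        })
        known = {k: v for k, v in payload.items() if k in cls.__dataclass_fields__}
        if "metrics" in known:
            known["metrics"] = tuple(known["metrics"])
        return cls(sim=sim, **known)


def activity_quartiles(activity: pd.Series) -> dict:
    """Quartile cutpoints of transcriptional activity with the middle two
    quartiles merged into one stratum: low (<= Q1), mid, high (> Q3)."""
    q1, q3 = float(activity.quantile(0.25)), float(activity.quantile(0.75))

    def label(x: float) -> str:
        if x <= q1:
            return "low"
        return "high" if x > q3 else "mid"

    return {"q1": q1, "q3": q3, "label": label}


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full analysis on a simulated cohort; returns the summary dict
    (also written as summary.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.sim.seed
    summary: dict = {"seed": seed}

    with _stage("simulate"):
        logfc, meta, truth = generate_training_cohort(config.sim)
        write_logfc(logfc, out / "logfc_train.tsv")
        write_meta(meta, out / "meta_train.tsv")
        logfc2, meta2, shift = generate_cross_system_cohort(config.sim, truth,
                                                            system=config.cross_system)
        write_logfc(logfc2, out / f"logfc_{config.cross_system}.tsv")
        write_meta(meta2, out / f"meta_{config.cross_system}.tsv")

    with _stage("modules"):
        models = network.build_module_models(logfc.subset_genes(
            _varying_genes(logfc)))
        network.save_modules(models, out / "modules.tsv", out / "modules.json")
        scores = network.training_scores(models, logfc)
        scores.to_csv(out / "module_scores.tsv", sep="\t", float_format="%.6g")
        activity = network.avg_abs_eg(scores, models)
        activity.rename("avg_abs_eg").to_frame().to_csv(out / "activity.tsv", sep="\t")
        summary["n_modules"] = len(models)
        summary["n_base_modules"] = int(sum(m.is_base for m in models))

    with _stage("gsa"):
        gene_sets = generate_gene_sets(truth, config.n_aligned_sets, config.n_random_sets)
        write_gmt(gene_sets, out / "gene_sets.gmt")
        zmat, _, padj = page_zscore_matrix(logfc, gene_sets)
        zmat.to_csv(out / "gsa_z.tsv", sep="\t", float_format="%.6g")
        padj.to_csv(out / "gsa_padj.tsv", sep="\t", float_format="%.6g")

    spaces = {"genes": logfc.frame, "gene_sets": zmat, "modules": scores}

    with _stage("concord"):
        pairs = generate_same_drug_pairs(config.sim, meta, truth)
        act = activity
        pairs["min_activity"] = np.minimum(act[pairs.experiment_a].to_numpy(),
                                           act[pairs.experiment_b].to_numpy())
        pairs["max_activity"] = np.maximum(act[pairs.experiment_a].to_numpy(),
                                           act[pairs.experiment_b].to_numpy())
        for space, profiles in spaces.items():
            conc = pair_concordance(profiles, pairs[["experiment_a", "experiment_b"]],
                                    metrics=config.metrics, frac=config.frac)
            for metric in config.metrics:
                pairs[f"{metric}_{space}"] = conc[metric].to_numpy()
        pairs.to_csv(out / "pairs_concordance.tsv", sep="\t", index=False,
                     float_format="%.6g")

    with _stage("selfid"):
        nulls = {}
        selfid_rows = []
        for space, profiles in spaces.items():
            null = build_null(profiles, meta, activity, metrics=config.metrics,
                              n_per_bin=config.n_per_bin,
                              seed=int(substream(seed, f"null_{space}").integers(2**31)),
                              frac=config.frac, allow_empty=True)
            nulls[space] = null
            for metric in config.metrics:
                col = f"{metric}_{space}"
                probs = [
                    self_id_probability(v, metric, a_min, null)
                    for v, a_min in zip(pairs[col], pairs["min_activity"])
                ]
                selfid_rows.append(pd.DataFrame({
                    "experiment_a": pairs.experiment_a, "experiment_b": pairs.experiment_b,
                    "space": space, "metric": metric, "concordance": pairs[col],
                    "min_activity": pairs["min_activity"], "probability": probs,
                    "success": [self_id_success(p) if np.isfinite(p) else False for p in probs],
                }))
        selfid = pd.concat(selfid_rows, ignore_index=True)
        selfid.to_csv(out / "selfid.tsv", sep="\t", index=False, float_format="%.6g")
        _write_null_tables(nulls, out / "null_tables.tsv", out / "null_tables.json")
        summary["selfid_success_rate"] = {
            f"{metric}_{space}": float(
                selfid.query("space == @space and metric == @metric")["success"].mean())
            for space in spaces for metric in config.metrics
        }

    with _stage("vardecomp"):
        decomp = {}
        for space in spaces:
            for metric in config.metrics:
                res = stepwise_fit(pairs, response=f"{metric}_{space}")
                decomp[f"{metric}_{space}"] = res
        table = pd.concat(
            {k: v.as_frame("fixed").set_index("covariate")["added_r2_percent"]
             for k, v in decomp.items()}, axis=1)
        table.to_csv(out / "vardecomp.tsv", sep="\t", float_format="%.4g")
        entry = pd.DataFrame({k: pd.Series(v.entry_order()) for k, v in decomp.items()})
        entry.to_csv(out / "vardecomp_entry_order.tsv", sep="\t", index=False)
        summary["vardecomp_total_r2"] = {k: v.total_r2 for k, v in decomp.items()}

    with _stage("stringency"):
        meta2_idx = meta2.set_index("experiment_id", drop=False)
        both = pd.concat([spaces["modules"],
                          network.score_matrix(logfc2, models)], axis=1)
        rows = []
        for eid in meta2["experiment_id"]:
            rec = {"query": eid}
            for lname, level in LEVELS.items():
                ref, val = best_match(eid, both, meta2_idx.loc[eid], meta,
                                      level, metric="pearson")
                rec[f"best_{lname}"] = ref
                rec[f"value_{lname}"] = val
            rows.append(rec)
        stringency = pd.DataFrame(rows)
        stringency.to_csv(out / "best_match.tsv", sep="\t", index=False,
                          float_format="%.6g")
        ok = stringency.dropna(subset=["value_L1"])
        summary["best_match_monotone"] = bool(
            ((ok["value_L2"] >= ok["value_L1"] - 1e-12)
             & (ok["value_L3"] >= ok["value_L2"] - 1e-12)).all())

    with _stage("report"):
        quart = activity_quartiles(activity)
        summary["activity_quartiles"] = {"q1": quart["q1"], "q3": quart["q3"]}
        strata = pairs["min_activity"].map(quart["label"])
        strat_summary = pairs.groupby(strata)[
            [f"{m}_{s}" for s in spaces for m in config.metrics]].mean()
        strat_summary.to_csv(out / "concordance_by_stratum.tsv", sep="\t",
                             float_format="%.6g")
        if config.make_figures:
            _figure(strat_summary, out / "concordance_by_stratum.png")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=float)
    return summary


def _varying_genes(logfc: LogFCMatrix) -> list:
    sd = logfc.frame.std(axis=1)
    return list(logfc.genes[sd > 0])


def _write_null_tables(nulls: dict, tsv_path, json_path) -> None:
    rows = []
    meta = {}
    for space, null in nulls.items():
        meta[space] = {"seed": null.seed, "bin_edges": list(null.bin_edges),
                       "counts": {str(k): v for k, v in null.counts.items()},
                       "sparse_bins": null.sparse_bins, "empty_bins": null.empty_bins}
        for (b, metric), vals in null.values.items():
            for v in vals:
                rows.append((space, b, metric, v))
    pd.DataFrame(rows, columns=["space", "bin", "metric", "value"]).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.6g")
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def _figure(strat_summary: pd.DataFrame, path) -> None:  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = strat_summary.loc[[s for s in ("low", "mid", "high")
                            if s in strat_summary.index]].plot.bar(figsize=(9, 4))
    ax.set_ylabel("mean concordance")
    ax.set_xlabel("activity stratum (min avg. abs. EG)")
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()
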