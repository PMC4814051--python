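"""Pairwise concordance of expression profiles, in any feature space.

Two experiments are compared over the intersection of their feature ids
(genes, gene-set z-scores, or module scores) using the Pearson correlation,
the percent overlap of the top 5% most differentially expressed features with
matching direction of change, or the Euclidean distance. Same-drug pair
enumeration and stringency-matched best-pair selection mirror the comparison
design used for cross-source and cross-system lookups.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_SPACES = ("genes", "gene_sets", "modules")
SIMILARITY_METRICS = ("pearson", "overlap")
DISTANCE_METRICS = ("euclidean",)


@dataclass(frozen=True)
class StringencyLevel:
    """Nested dose/time constraints for matching experiments.

    L1: same time point (optionally within 1.15-fold) and <= 5-fold dose
    difference; L2: <= 2-fold time and <= 10-fold dose; L3: unconstrained.
    """

    name: str
    max_time_ratio: float
    max_dose_ratio: float

    def eligible(self, time_ratio: float, dose_ratio: float) -> bool:
        return time_ratio <= self.max_time_ratio and dose_ratio <= self.max_dose_ratio


L1 = StringencyLevel("L1", 1.0, 5.0)
L1_RELAXED = StringencyLevel("L1", 1.15, 5.0)  # allows 7 vs 8 day comparisons
L2 = StringencyLevel("L2", 2.0, 10.0)
L3 = StringencyLevel("L3", math.inf, math.inf)
LEVELS = {"L1": L1, "L2": L2, "L3": L3}


def _shared(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    common = a.index.intersection(b.index)
    return a.loc[common].to_numpy(dtype=float), b.loc[common].to_numpy(dtype=float)


def pearson_concordance(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation over shared features; NaN (with a warning) when a
    profile is constant over the intersection."""
    x, y = _shared(a, b)
    if len(x) < 3:
        raise ValueError(f"need >= 3 shared features, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant profile: Pearson concordance undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def top_k_size(n_features: int, frac: float = 0.05) -> int:
    """Top-list size = round-half-up(frac * N); 9071 genes -> 454, 415
    modules -> 21. Floored at one feature so tiny spaces stay comparable."""
    return max(1, int(math.floor(frac * n_features + 0.5)))


def top_k_set(profile: pd.Series, frac: float = 0.05) -> dict:
    """The top-|value| fraction of features with their direction of change.

    Direction ignores magnitude rank: sign(value), zeros counted positive.
    Ties at the boundary break on feature id (deterministic).
    """
    k = top_k_size(len(profile), frac)
    order = sorted(profile.index, key=lambda f: (-abs(profile[f]), str(f)))
    return {f: (1 if profile[f] >= 0 else -1) for f in order[:k]}


def percent_overlap(a: pd.Series, b: pd.Series, frac: float = 0.05) -> float:
    """Percent of top-fraction features shared by both experiments and
    changing in the same direction, relative to the top-list size."""
    common = a.index.intersection(b.index)
    ta = top_k_set(a.loc[common], frac)
    tb = top_k_set(b.loc[common], frac)
    k = top_k_size(len(common), frac)
    if k == 0:
        raise ValueError("top list is empty; profile too short for this fraction")
    hits = sum(1 for f, s in ta.items() if f in tb and tb[f] == s)
    return 100.0 * hits / k

def euclidean_concordance(a: pd.Series, b: pd.Series) -> float:
    """L2 distance over shared features; identical profiles score 0."""
    x, y = _shared(a, b)
    return float(np.linalg.norm(x - y))


METRIC_FUNCS = {
    "pearson": pearson_concordance,
    "overlap": percent_overlap,
    "euclidean": euclidean_concordance,
}


def is_distance(metric: str) -> bool:
    return metric in DISTANCE_METRICS


def _ratio_covariates(row_a: pd.Series, row_b: pd.Series) -> dict:
    dose_ratio = max(row_a.dose, row_b.dose) / min(row_a.dose, row_b.dose)
    time_ratio = max(row_a.time_h, row_b.time_h) / min(row_a.time_h, row_b.time_h)
    if row_a.schedule == row_b.schedule:
        sched = "both_single" if row_a.schedule == "single" else "both_repeat"
    else:
        sched = "mixed"
    return {
        "dose_ratio": dose_ratio,
        "time_ratio": time_ratio,
        "log10_dose_ratio": math.log10(dose_ratio),
        "log10_time_ratio": math.log10(time_ratio),
        "schedule_diff": sched,
    }


def enumerate_same_drug_pairs(
    meta: pd.DataFrame,
    cross_system: bool = False,
) -> pd.DataFrame:
    """All unordered pairs of experiments sharing a compound, with dose/time
    ratio covariates. With ``cross_system=True`` only pairs whose two
    experiments come from different systems are kept."""
    rows = []
    for _, grp in meta.groupby("compound", sort=False):
        recs = list(grp.itertuples(index=False))
        for a, b in itertools.combinations(recs, 2):
            if cross_system and a.system == b.system:
                continue
            cov = _ratio_covariates(a, b)
            rows.append({"experiment_a": a.experiment_id, "experiment_b": b.experiment_id,
                         "compound": a.compound, **cov})
    return pd.DataFrame(rows, columns=[
        "experiment_a", "experiment_b", "compound", "dose_ratio", "time_ratio",
        "log10_dose_ratio", "log10_time_ratio", "schedule_diff",
    ])


def pair_concordance(
    profiles: pd.DataFrame,
    pairs: pd.DataFrame,
    metrics=("pearson", "overlap"),
    frac: float = 0.05,
) -> pd.DataFrame:
    """Append a column per concordance metric to a pair table.

    ``profiles`` is features x experiments (any feature space). Pearson and
    Euclidean are computed vectorized; overlap from per-experiment top lists.
    """
    out = pairs.copy()
    X = profiles.to_numpy(dtype=float)
    col = {e: i for i, e in enumerate(profiles.columns)}
    ia = pairs["experiment_a"].map(col).to_numpy()
    ib = pairs["experiment_b"].map(col).to_numpy()
    if "pearson" in metrics:
        Xc = X - X.mean(axis=0, keepdims=True)
        norm = np.linalg.norm(Xc, axis=0)
        norm[norm == 0] = np.nan
        Xn = Xc / norm
        out["pearson"] = np.einsum("ij,ij->j", Xn[:, ia], Xn[:, ib])
    if "euclidean" in metrics:
        out["euclidean"] = np.linalg.norm(X[:, ia] - X[:, ib], axis=0)
    if "overlap" in metrics:
        k = top_k_size(profiles.shape[0], frac)
        tops = {e: top_k_set(profiles[e], frac) for e in profiles.columns}
        vals = []
        for a, b in zip(pairs["experiment_a"], pairs["experiment_b"]):
            ta, tb = tops[a], tops[b]
            hits = sum(1 for f, s in ta.items() if f in tb and tb[f] == s)
            vals.append(100.0 * hits / k)
        out["overlap"] = vals
    return out


def best_match(
    query_id: str,
    profiles: pd.DataFrame,
    query_meta: pd.Series,
    ref_meta: pd.DataFrame,
    level: StringencyLevel,
    metric: str = "pearson",
    frac: float = 0.05,
):
    """The most concordant eligible same-drug reference experiment.

    Eligibility = same compound, dose/time ratios within the stringency
    bounds. Similarity metrics are maximized, distances minimized. Returns
    (reference experiment id, concordance value), or (None, nan) when no
    reference is eligible (logged).
    """
    fn = METRIC_FUNCS[metric]
    candidates = ref_meta[ref_meta["compound"] == query_meta["compound"]]
    best_id, best_val = None, float("nan")
    qa = profiles[query_id]
    for rec in candidates.itertuples(index=False):
        if rec.experiment_id == query_id:
            continue
        cov = _ratio_covariates(query_meta, pd.Series(rec._asdict()))
        if not level.eligible(cov["time_ratio"], cov["dose_ratio"]):
            continue
        val = fn(qa, profiles[rec.experiment_id], frac) if metric == "overlap" else fn(qa, profiles[rec.experiment_id])
        if math.isnan(val):
            continue
        better = val < best_val if is_distance(metric) else val > best_val
        if best_id is None or better:
            best_id, best_val = rec.experiment_id, val
    if best_id is None:
        logger.info("no eligible reference for %s at level %s", query_id, level.name)
    return best_id, best_val
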