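"""Parametric gene-set analysis (PAGE-style z-scores).

For one experiment's per-gene logFC vector x and a gene set S of size m,

    z(S) = (mean(x[S]) - mean(x)) * sqrt(m) / sd(x)

with sd the sample (n-1) standard deviation over *all* genes on the array.
Under a null where S is a random draw from the profile, z is approximately
standard normal; two-sided normal tail probabilities are BH-adjusted per
experiment. Collections are pruned to sets recurrently significant across a
cohort, with a rescue list added back regardless of significance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import GeneSetCollection, LogFCMatrix

logger = logging.getLogger(__name__)


def page_zscores(
    profile: pd.Series,
    sets: GeneSetCollection,
    min_present: int = 3,
) -> pd.DataFrame:
    """Per-set enrichment z and two-sided p for one experiment.

    Set members absent from the profile are dropped before computing the set
    size m; sets with fewer than ``min_present`` present members are flagged
    missing (NaN), not zero.
    """
    x = profile.to_numpy(dtype=float)
    mu_all = x.mean()
    sd_all = x.std(ddof=1)
    if sd_all == 0:
        name = profile.name if profile.name is not None else "<unnamed>"
        raise ValueError(f"experiment {name}: profile has zero variance, z undefined")
    index = profile.index
    pos = {g: i for i, g in enumerate(index)}
    rows = []
    for s in sets:
        idx = [pos[g] for g in s.members if g in pos]
        m = len(idx)
        if m < min_present:
            rows.append((s.name, np.nan, np.nan, m, True))
            continue
        mu_set = x[idx].mean()
        z = (mu_set - mu_all) * np.sqrt(m) / sd_all
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((s.name, z, p, m, False))
    return pd.DataFrame(rows, columns=["set", "z", "p", "m", "missing"]).set_index("set")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving). NaNs pass
    through untouched."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def page_zscore_matrix(
    logfc: LogFCMatrix,
    sets: GeneSetCollection,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """z, raw p and BH-adjusted p matrices (sets x experiments) for a cohort.

    BH adjustment is applied within each experiment, across sets.
    """
    zcols, pcols, acols = {}, {}, {}
    for eid in logfc.experiments:
        res = page_zscores(logfc.profile(eid), sets)
        zcols[eid] = res["z"]
        pcols[eid] = res["p"]
        acols[eid] = pd.Series(bh_adjust(res["p"].to_numpy()), index=res.index)
    names = sets.names()
    zmat = pd.DataFrame(zcols).loc[names]
    pmat = pd.DataFrame(pcols).loc[names]
    padj = pd.DataFrame(acols).loc[names]
    return zmat, pmat, padj


def prune_gene_sets(
    padj: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.01,
    min_frac: float = 0.01,
    rescue: tuple = (),
) -> GeneSetCollection:
    """Keep sets with adjusted p <= alpha in >= min_frac of experiments, then
    union in the rescue list (domain-relevant sets added back regardless)."""
    sig_frac = (padj <= alpha).mean(axis=1)
    surviving = set(padj.index[sig_frac >= min_frac])
    rescued = set(rescue)
    unknown = rescued - set(collection.names())
    if unknown:
        raise ValueError(f"rescue list names not in collection: {sorted(unknown)}")
    keep = surviving | rescued
    kept = [s for s in collection if s.name in keep]
    logger.info("pruning kept %d surviving + %d rescued = %d gene sets",
                len(surviving), len(rescued - surviving), len(kept))
    return GeneSetCollection(kept)
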