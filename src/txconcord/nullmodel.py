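"""Activity-binned random-pair null and the self-identification rule.

The concordance of random pairs of experiments involving *different* drugs
rises with the pair's transcriptional activity (a shared stress-response axis
makes strongly perturbing treatments look alike). Self-identification of a
same-drug pair must therefore beat activity-matched random pairs: the pair's
activity (the smaller of the two experiments' avg. abs. EG, i.e. the least
perturbing treatment) selects one of 7 activity bins, and the self-ID
probability is the fraction of that bin's random-pair null values at least as
concordant as the observed pair. Success requires fewer than 5% of random
pairs to match or exceed it (strict < 0.05).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import is_distance, pair_concordance

logger = logging.getLogger(__name__)

#: interior edges of the 7 left-closed activity intervals:
#: [0, 0.2), [0.2, 0.3), [0.3, 0.4), [0.4, 0.5), [0.5, 0.6), [0.6, 0.8), [0.8, inf)
ACTIVITY_BIN_EDGES = (0.2, 0.3, 0.4, 0.5, 0.6, 0.8)


def assign_activity_bin(pair_activity, edges=ACTIVITY_BIN_EDGES):
    """1-based bin index under the left-closed, right-open convention
    (0.2 falls in bin 2; >= last edge in the top bin)."""
    return np.searchsorted(np.asarray(edges), np.asarray(pair_activity), side="right") + 1


@dataclass
class NullTable:
    """Per-bin empirical null distributions of random different-drug pair
    concordance, one sorted array per (bin, metric)."""

    bin_edges: tuple
    values: dict  # (bin_index, metric) -> sorted np.ndarray
    counts: dict  # bin_index -> number of pairs used
    seed: int
    sparse_bins: list = field(default_factory=list)
    empty_bins: list = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) + 1


def build_null(
    profiles: pd.DataFrame,
    meta: pd.DataFrame,
    activity: pd.Series,
    metrics=("pearson", "overlap"),
    n_per_bin: int = 1000,
    seed: int = 0,
    frac: float = 0.05,
    bin_edges=ACTIVITY_BIN_EDGES,
    allow_empty: bool = False,
) -> NullTable:
    """Empirical null from random different-drug pairs, binned on pair activity.

    All eligible different-drug pairs are enumerated, assigned to activity
    bins via the smaller of the two experiments' activity, and up to
    ``n_per_bin`` pairs per bin are sampled without replacement (experiments
    may recur across pairs). Bins with fewer available pairs use them all with
    a warning; an empty bin is an error unless ``allow_empty``.
    """
    rng = np.random.default_rng(seed)
    meta = meta.set_index("experiment_id")
    exp_ids = [e for e in profiles.columns if e in meta.index]
    compounds = meta.loc[exp_ids, "compound"]
    act = activity.loc[exp_ids]

    bins: dict = {b: [] for b in range(1, len(bin_edges) + 2)}
    for a, b in itertools.combinations(exp_ids, 2):
        if compounds[a] == compounds[b]:
            continue
        pair_act = min(act[a], act[b])
        bins[int(assign_activity_bin(pair_act, bin_edges))].append((a, b))

    values: dict = {}
    counts: dict = {}
    sparse, empty = [], []
    for b, pairs in bins.items():
        if not pairs:
            empty.append(b)
            if not allow_empty:
                raise ValueError(f"activity bin {b} contains no different-drug pairs")
            for metric in metrics:
                values[(b, metric)] = np.array([])
            counts[b] = 0
            continue
        if len(pairs) < n_per_bin:
            sparse.append(b)
            logger.warning("bin %d has only %d different-drug pairs (< %d); using all",
                           b, len(pairs), n_per_bin)
            chosen = pairs
        else:
            idx = rng.choice(len(pairs), size=n_per_bin, replace=False)
            chosen = [pairs[i] for i in idx]
        table = pd.DataFrame(chosen, columns=["experiment_a", "experiment_b"])
        table["compound"] = ""  # unused by pair_concordance
        conc = pair_concordance(profiles, table, metrics=metrics, frac=frac)
        for metric in metrics:
            values[(b, metric)] = np.sort(conc[metric].to_numpy())
        counts[b] = len(chosen)
    return NullTable(bin_edges=tuple(bin_edges), values=values, counts=counts,
                     seed=seed, sparse_bins=sparse, empty_bins=empty)


def self_id_probability(
    observed: float,
    metric: str,
    pair_activity: float,
    null: NullTable,
) -> float:
    """Fraction of the activity-matched null at least as concordant as the
    observed value (<= for distance metrics, >= otherwise). NaN when the
    pair's bin holds no null pairs."""
    b = int(assign_activity_bin(pair_activity, null.bin_edges))
    vals = null.values[(b, metric)]
    if len(vals) == 0:
        return float("nan")
    if is_distance(metric):
        n_beat = np.searchsorted(vals, observed, side="right")
    else:
        n_beat = len(vals) - np.searchsorted(vals, observed, side="left")
    return float(n_beat / len(vals))


def self_id_success(probability: float) -> bool:
    """Success iff strictly fewer than 5% of random pairs match or beat the
    observed concordance."""
    return bool(probability < 0.05)
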