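"""Core data model: experiments, fold-change matrices, intensities, gene sets.

An *experiment* is one treatment condition (compound / dose / time / schedule /
system / source) whose expression readout has been normalized to time-matched
controls. The universal feature substrate downstream is the log10 fold-change
matrix (genes x experiments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEDULES = ("single", "repeat")
SYSTEMS = ("rat_liver", "mouse_liver", "human_liver", "RPH", "MPH", "HPH", "HepG2")

#: canonical column order for experiment metadata tables
META_COLUMNS = [
    "experiment_id",
    "compound",
    "dose",
    "time_h",
    "schedule",
    "system",
    "source",
    "n_treated",
    "n_control",
]


@dataclass(frozen=True)
class ExperimentMeta:
    """One treatment condition. Dose units are mg/kg in vivo, uM in vitro."""

    experiment_id: str
    compound: str
    dose: float
    time_h: float
    schedule: str
    system: str
    source: str = "synthetic"
    n_treated: int = 3
    n_control: int = 3

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError(f"{self.experiment_id}: dose must be > 0, got {self.dose}")
        if self.time_h <= 0:
            raise ValueError(f"{self.experiment_id}: time must be > 0, got {self.time_h}")
        if self.schedule not in SCHEDULES:
            raise ValueError(f"{self.experiment_id}: schedule must be one of {SCHEDULES}")
        if self.system not in SYSTEMS:
            raise ValueError(f"{self.experiment_id}: system must be one of {SYSTEMS}")
        if self.n_treated < 1 or self.n_control < 1:
            raise ValueError(f"{self.experiment_id}: replicate counts must be >= 1")


def meta_frame(experiments: Iterable[ExperimentMeta]) -> pd.DataFrame:
    """Assemble a metadata table (one row per experiment) from records."""
    rows = [vars(e) for e in experiments]
    df = pd.DataFrame(rows, columns=META_COLUMNS)
    validate_meta(df)
    return df


def validate_meta(df: pd.DataFrame) -> None:
    """Enforce metadata invariants; errors carry row coordinates."""
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing required columns: {missing}")
    dup = df["experiment_id"][df["experiment_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate experiment ids: {sorted(dup.unique())}")
    for col, pred in (("dose", df["dose"] <= 0), ("time_h", df["time_h"] <= 0)):
        if pred.any():
            rows = df.index[pred].tolist()
            raise ValueError(f"column {col!r} must be positive; offending rows: {rows}")
    bad = ~df["schedule"].isin(SCHEDULES)
    if bad.any():
        raise ValueError(
            f"column 'schedule' must be in {SCHEDULES}; offending rows: {df.index[bad].tolist()}"
        )


class LogFCMatrix:
    """Genes x experiments matrix of log10 fold changes (treatment vs control)."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if frame.columns.duplicated().any():
            dups = frame.columns[frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate experiment ids: {dups}")
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            coords = [(frame.index[i], frame.columns[j]) for i, j in bad[:5]]
            raise ValueError(f"non-finite fold-change values at {coords}")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    @property
    def experiments(self) -> pd.Index:
        return self.frame.columns

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def profile(self, experiment_id: str) -> pd.Series:
        """One experiment's per-gene logFC vector."""
        return self.frame[experiment_id]

    def subset_genes(self, gene_ids: Sequence[str]) -> "LogFCMatrix":
        return LogFCMatrix(self.frame.loc[list(gene_ids)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LogFCMatrix({self.frame.shape[0]} genes x {self.frame.shape[1]} experiments)"


class IntensityMatrix:
    """Per-array log intensities with a control/treatment arm label per array."""

    def __init__(self, frame: pd.DataFrame, arm: Mapping[str, str] | pd.Series):
        arm = pd.Series(dict(arm) if not isinstance(arm, pd.Series) else arm)
        missing = [a for a in frame.columns if a not in arm.index]
        if missing:
            raise ValueError(f"arrays without an arm label: {missing}")
        bad = arm.loc[frame.columns][~arm.loc[frame.columns].isin(["control", "treatment"])]
        if len(bad):
            raise ValueError(f"arm labels must be control|treatment; offenders: {bad.to_dict()}")
        self.frame = frame.astype(float)
        self.arm = arm.loc[frame.columns]

    @property
    def feature_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def array_ids(self) -> pd.Index:
        return self.frame.columns

    def arrays(self, arm: str) -> pd.DataFrame:
        """Submatrix of arrays in the given arm."""
        return self.frame.loc[:, self.arm[self.arm == arm].index]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple
    category: str = "custom"  # CP | GO | custom
    description: str = ""

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """An ordered collection of named gene sets (GMT-shaped)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets = list(sets)
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dup}")
        self._by_name = {s.name: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def names(self) -> list:
        return [s.name for s in self.sets]

    def filter_by_size(self, min_size: int = 3, max_size: int = 5000) -> "GeneSetCollection":
        """Drop sets outside [min_size, max_size]; rejected sets are logged."""
        kept, rejected = [], []
        for s in self.sets:
            if min_size <= len(s.members) <= max_size:
                kept.append(s)
            else:
                rejected.append(s.name)
        if rejected:
            logger.warning(
                "rejected %d gene sets outside size range [%d, %d]: %s",
                len(rejected), min_size, max_size, rejected[:10],
            )
        return GeneSetCollection(kept)


class OrthologMap:
    """Relation between a reference organism's gene ids and another organism's.

    Lookups on unmapped ids return ``None`` (an explicit missing marker).
    """

    def __init__(self, pairs: Iterable[tuple], reference: str = "rat"):
        self.reference = reference
        self._to_ref: dict = {}
        for ref_id, other_id in pairs:
            self._to_ref[str(other_id)] = str(ref_id)

    def to_reference(self, other_id: str):
        return self._to_ref.get(str(other_id))

    def translate(self, ids: Sequence[str]) -> list:
        """Map ids to the reference organism; unmapped ids become None."""
        return [self._to_ref.get(str(i)) for i in ids]

    def __len__(self) -> int:
        return len(self._to_ref)


# ---------------------------------------------------------------------------
# operations


def normalize_to_controls(
    intensities: IntensityMatrix,
    treated_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Per-gene logFC: mean log intensity over treated minus mean over controls.

    By default the arms recorded in ``intensities`` define the groups; explicit
    array id lists override them (they must be subsets of the matrix columns).
    """
    if treated_ids is None:
        treated_ids = list(intensities.arrays("treatment").columns)
    if control_ids is None:
        control_ids = list(intensities.arrays("control").columns)
    if len(treated_ids) == 0:
        raise ValueError("treatment arm is empty")
    if len(control_ids) == 0:
        raise ValueError("control arm is empty")
    missing = [a for a in list(treated_ids) + list(control_ids) if a not in intensities.frame.columns]
    if missing:
        raise ValueError(f"array ids not present in the intensity matrix: {missing}")
    treated = intensities.frame[list(treated_ids)].mean(axis=1)
    control = intensities.frame[list(control_ids)].mean(axis=1)
    out = treated - control
    out.name = "logfc"
    return out


def select_representative_probeset(
    intensities: IntensityMatrix,
    probe_to_gene: Mapping[str, Sequence[str] | str],
) -> dict:
    """Pick one representative probe set per gene: the one with the highest
    mean control-arm intensity. Probes mapping to more than one gene are
    discarded before selection; ties break on lexicographic probe id.
    """
    controls = intensities.arrays("control")
    if controls.shape[1] == 0:
        raise ValueError("no control arrays available for probe selection")
    gene_probes: dict = {}
    for probe, genes in probe_to_gene.items():
        genes = [genes] if isinstance(genes, str) else list(genes)
        if len(set(genes)) != 1:
            continue  # ambiguous probe: maps to multiple genes
        if probe not in controls.index:
            continue
        gene_probes.setdefault(genes[0], []).append(probe)
    mean_int = controls.mean(axis=1)
    out = {}
    for gene, probes in gene_probes.items():
        # sort keeps ties deterministic (lexicographic probe id)
        best = max(sorted(probes), key=lambda p: mean_int[p])
        out[gene] = best
    dropped = set()
    for probe, genes in probe_to_gene.items():
        genes = [genes] if isinstance(genes, str) else list(genes)
        dropped.update(g for g in genes if g not in out)
    if dropped:
        logger.info("genes without a surviving probe set: %s", sorted(dropped)[:10])
    return out
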