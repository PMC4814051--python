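"""TSV / GMT readers and writers.

Canonical matrix dialect: tab-separated with a header row, first column the
feature id, numbers formatted to 6 significant digits (human-diffable and
git-friendly). GMT follows the Broad dialect: name, description, members.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .data import (
    GeneSet,
    GeneSetCollection,
    IntensityMatrix,
    LogFCMatrix,
    META_COLUMNS,
    OrthologMap,
    validate_meta,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        for col in non_numeric:
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ValueError(f"non-numeric cells in column {col!r}, rows {bad_rows[:5]}")
    return df


def read_logfc(path) -> LogFCMatrix:
    return LogFCMatrix(_read_matrix(path))


def write_logfc(matrix: LogFCMatrix, path) -> None:
    matrix.frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene_id")


def read_meta(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    validate_meta(df)
    return df


def write_meta(meta: pd.DataFrame, path) -> None:
    validate_meta(meta)
    meta.to_csv(path, sep="\t", index=False)


def read_intensities(matrix_path, arms_path) -> IntensityMatrix:
    """Intensity matrix (features x arrays) plus a two-column arm table
    (array_id, arm)."""
    frame = _read_matrix(matrix_path)
    arms = pd.read_csv(arms_path, sep="\t")
    if list(arms.columns[:2]) != ["array_id", "arm"]:
        raise ValueError("arm table must have columns: array_id, arm")
    return IntensityMatrix(frame, arms.set_index("array_id")["arm"])


def write_intensities(intensities: IntensityMatrix, matrix_path, arms_path) -> None:
    intensities.frame.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT, index_label="feature_id")
    arm = intensities.arm.rename_axis("array_id").rename("arm").reset_index()
    arm.to_csv(arms_path, sep="\t", index=False)


def read_gmt(path, min_size: int = 3, max_size: int = 5000) -> GeneSetCollection:
    """Read a GMT file, applying the standard size filter; undersized or
    oversized sets are rejected with a warning."""
    sets = []
    rejected = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, description, >=1 member")
            name, description, *members = parts
            members = [m for m in members if m]
            if not (min_size <= len(members) <= max_size):
                rejected.append(name)
                continue
            sets.append(GeneSet(name=name, description=description, members=tuple(members)))
    if rejected:
        logger.warning("rejected %d GMT sets outside size [%d, %d]: %s",
                       len(rejected), min_size, max_size, rejected[:10])
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or s.category, *s.members]) + "\n")


def read_ortholog_map(path, reference: str = "rat") -> OrthologMap:
    """Two-column TSV: reference gene id, other-organism gene id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns: reference_id, other_id")
    pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return OrthologMap(pairs, reference=reference)


def write_ortholog_map(mapping: OrthologMap, path) -> None:
    rows = [(ref, other) for other, ref in mapping._to_ref.items()]
    pd.DataFrame(rows, columns=[f"{mapping.reference}_id", "other_id"]).to_csv(
        path, sep="\t", index=False
    )
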