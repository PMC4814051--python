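"""Co-expression modules in fold-change space, with scale-not-center scoring.

Modules are derived on a training logFC matrix: soft-thresholded unsigned
adjacency |cor|^power, topological overlap (TOM) similarity, average-linkage
clustering of 1 - TOM, and a height-adaptive branch cut with a minimum module
size. Each module is calibrated by PCA on the z-scored member submatrix; the
first-PC gene loadings and the per-gene training mean/sd are stored, along
with the standard deviation of raw module scores across training experiments.

Scoring a new experiment deliberately *scales but does not center* the logFC
values: raw = sum over members of loading * (logFC / train_sd), divided by the
training raw-score sd. Centering at scoring time would let an experiment with
near-zero fold changes take on spurious nonzero module scores, because many
genes have nonzero mean logFC across a toxicology training cohort; skipping it
makes the all-zero profile score exactly zero on every module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .data import LogFCMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleMember:
    gene_id: str
    loading: float
    train_mean: float
    train_sd: float


@dataclass
class ModuleModel:
    """A calibrated co-expression module."""

    module_id: str
    members: list  # of ModuleMember
    raw_score_sd: float
    pc1_variance_fraction: float
    kind: str = "unmerged"  # unmerged | merged
    is_base: bool = True
    constituents: list = field(default_factory=list)  # module ids, for merged modules

    def __post_init__(self) -> None:
        if self.raw_score_sd <= 0:
            raise ValueError(f"{self.module_id}: raw_score_sd must be > 0")
        for m in self.members:
            if m.train_sd <= 0:
                raise ValueError(f"{self.module_id}: gene {m.gene_id} has train_sd <= 0")

    @property
    def gene_ids(self) -> list:
        return [m.gene_id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ModuleScore:
    score: float
    coverage: float
    low_confidence: bool


# ---------------------------------------------------------------------------
# network construction


def soft_adjacency(logfc_train: LogFCMatrix, power: int = 8) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency a_ij = |cor(g_i, g_j)|^power.

    Unsigned means anti-correlated genes are fully adjacent: a module may
    contain both induced and repressed genes.
    """
    X = logfc_train.values
    sd = X.std(axis=1)
    if (sd == 0).any():
        dead = logfc_train.genes[sd == 0].tolist()
        raise ValueError(f"genes with zero variance cannot enter the network: {dead[:10]}")
    corr = np.corrcoef(X)
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=logfc_train.genes, columns=logfc_train.genes)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap:
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), k_i = sum_{u!=i} a_iu.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # u = i or j contribute zero with the zeroed diagonal
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _adaptive_cut(Z: np.ndarray, n: int, min_size: int, cut_height: float, gap: float):
    """Height-adaptive branch decomposition of an average-linkage dendrogram.

    First separate maximal branches fully merged below ``cut_height``; then
    recursively split a branch at its root merge whenever both children hold
    >= min_size leaves and the merge height exceeds the taller child's merge
    height by a relative gap. Branches smaller than min_size stay unassigned.
    """
    root = to_tree(Z)

    def leaves(node):
        out, stack = [], [node]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                out.append(nd.id)
            else:
                stack.extend([nd.left, nd.right])
        return out

    # maximal subtrees below the static cut
    branches, stack = [], [root]
    while stack:
        nd = stack.pop()
        if nd.is_leaf() or nd.dist <= cut_height:
            branches.append(nd)
        else:
            stack.extend([nd.left, nd.right])

    clusters, stack = [], list(branches)
    while stack:
        nd = stack.pop()
        if nd.is_leaf() or nd.count < 2 * min_size:
            clusters.append(nd)
            continue
        L, R = nd.left, nd.right
        child_h = max(L.dist, R.dist)
        if L.count >= min_size and R.count >= min_size and (nd.dist - child_h) >= gap * max(nd.dist, 1e-12):
            stack.extend([L, R])
        else:
            clusters.append(nd)

    return [leaves(c) for c in clusters if c.count >= min_size]


def derive_modules(
    logfc_train: LogFCMatrix,
    min_cluster_size: int = 5,
    power: int = 8,
    cut_height: float | None = None,
    gap: float = 0.05,
) -> list:
    """Derive disjoint gene clusters (uncalibrated module memberships).

    Returns a list of gene-id lists, largest first; genes not in any cluster
    of size >= min_cluster_size remain unassigned.
    """
    if logfc_train.frame.shape[1] < 3:
        raise ValueError("need at least 3 training experiments to estimate correlations")
    if logfc_train.frame.shape[0] < min_cluster_size:
        raise ValueError("fewer genes than the minimum cluster size")
    adj = soft_adjacency(logfc_train, power=power)
    tom = tom_similarity(adj)
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0  # enforce exact symmetry before condensing
    Z = linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        cut_height = 0.99 * Z[:, 2].max()
    idx_clusters = _adaptive_cut(Z, diss.shape[0], min_cluster_size, cut_height, gap)
    genes = logfc_train.genes
    clusters = [sorted(genes[i] for i in idx) for idx in idx_clusters]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    logger.info("derived %d modules covering %d of %d genes",
                len(clusters), sum(map(len, clusters)), len(genes))
    return clusters


# ---------------------------------------------------------------------------
# calibration and scoring


def calibrate_module(
    gene_ids,
    logfc_train: LogFCMatrix,
    module_id: str,
    kind: str = "unmerged",
) -> ModuleModel:
    """Calibrate a module on training data.

    Member genes are z-scored (center and scale) across training experiments;
    the first principal component of that submatrix gives the gene loadings;
    raw training scores are the projections and their sd normalizes all later
    scoring. The loading sign is fixed so the loadings sum positive (fallback:
    the largest-|loading| gene positive).
    """
    sub = logfc_train.frame.loc[list(gene_ids)]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    if (sd <= 0).any():
        dead = sub.index[sd <= 0].tolist()
        raise ValueError(f"{module_id}: members with zero training sd: {dead}")
    Xz = ((sub.sub(mean, axis=0)).div(sd, axis=0)).to_numpy().T  # experiments x genes
    U, S, Vt = np.linalg.svd(Xz, full_matrices=False)
    loadings = Vt[0]
    if loadings.sum() < 0 or (loadings.sum() == 0 and loadings[np.argmax(np.abs(loadings))] < 0):
        loadings = -loadings
    raw_scores = Xz @ loadings
    raw_sd = float(np.std(raw_scores, ddof=1))
    if raw_sd <= 0:
        raise ValueError(f"{module_id}: degenerate training scores (sd = 0)")
    pc1 = float(S[0] ** 2 / (S**2).sum())
    members = [
        ModuleMember(g, float(l), float(mu), float(s))
        for g, l, mu, s in zip(sub.index, loadings, mean, sd)
    ]
    return ModuleModel(module_id=module_id, members=members, raw_score_sd=raw_sd,
                       pc1_variance_fraction=pc1, kind=kind)


def score_experiment(
    profile: pd.Series,
    model: ModuleModel,
    gene_sd: pd.Series | None = None,
    low_coverage: float = 0.6,
) -> ModuleScore:
    """Final module score for one experiment, in training-sd units.

    raw = sum over present members of loading * (logFC / sd); final = raw /
    raw_score_sd. No mean subtraction at scoring time. ``gene_sd`` optionally
    substitutes per-gene sds from another system (rescaling choice); the
    default uses the training sds stored in the model. A score with member
    coverage below ``low_coverage`` is flagged low-confidence; zero coverage
    yields a missing (NaN) score.
    """
    raw = 0.0
    present = 0
    for m in model.members:
        if m.gene_id not in profile.index:
            continue
        sd = m.train_sd if gene_sd is None else float(gene_sd.get(m.gene_id, np.nan))
        if not np.isfinite(sd) or sd <= 0:
            continue
        raw += m.loading * (profile[m.gene_id] / sd)
        present += 1
    coverage = present / len(model.members)
    if present == 0:
        logger.warning("%s: no member genes present in profile; score is missing", model.module_id)
        return ModuleScore(score=float("nan"), coverage=0.0, low_confidence=True)
    return ModuleScore(score=float(raw / model.raw_score_sd), coverage=coverage,
                       low_confidence=coverage < low_coverage)


def score_matrix(
    logfc: LogFCMatrix,
    models,
    gene_sd: pd.Series | None = None,
) -> pd.DataFrame:
    """Final module scores (modules x experiments) for a whole cohort."""
    frame = logfc.frame
    cols = {}
    for model in models:
        genes = [m.gene_id for m in model.members if m.gene_id in frame.index]
        if not genes:
            cols[model.module_id] = pd.Series(np.nan, index=frame.columns)
            continue
        w = np.array([m.loading for m in model.members if m.gene_id in frame.index])
        if gene_sd is None:
            sds = np.array([m.train_sd for m in model.members if m.gene_id in frame.index])
        else:
            sds = gene_sd.reindex(genes).to_numpy()
        weights = w / sds
        cols[model.module_id] = pd.Series(
            weights @ frame.loc[genes].to_numpy() / model.raw_score_sd, index=frame.columns
        )
    return pd.DataFrame(cols).T


def training_scores(models, logfc_train: LogFCMatrix) -> pd.DataFrame:
    """Final (uncentered) scores of the training experiments themselves."""
    return score_matrix(logfc_train, models)


def merge_modules(
    models,
    logfc_train: LogFCMatrix,
    r_threshold: float = 0.8,
) -> list:
    """Group modules whose training eigengene scores correlate R >= threshold.

    Connected components of the threshold graph are merged: each multi-module
    component is recalibrated as one merged module on the union gene set and
    becomes a base module; its constituents keep their definitions but lose
    base status. Modules outside any merge stay base, unmerged. Returns the
    updated originals followed by the merged modules.
    """
    models = [replace(m) for m in models]
    scores = training_scores(models, logfc_train)
    R = np.corrcoef(scores.to_numpy())
    adj = (R >= r_threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(adj, directed=False)
    out = list(models)
    merged_count = 0
    for comp in range(n_comp):
        idx = np.where(labels == comp)[0]
        if len(idx) < 2:
            models[idx[0]].is_base = True
            continue
        merged_count += 1
        union_genes = sorted({g for i in idx for g in models[i].gene_ids})
        merged = calibrate_module(union_genes, logfc_train,
                                  module_id=f"MG{merged_count:03d}", kind="merged")
        merged.is_base = True
        merged.constituents = [models[i].module_id for i in idx]
        for i in idx:
            models[i].is_base = False
        out.append(merged)
    logger.info("merged %d groups; %d base modules of %d total",
                merged_count, sum(m.is_base for m in out), len(out))
    return out


def build_module_models(
    logfc_train: LogFCMatrix,
    min_cluster_size: int = 5,
    power: int = 8,
    r_threshold: float = 0.8,
) -> list:
    """Derive, calibrate and merge modules on a training cohort."""
    clusters = derive_modules(logfc_train, min_cluster_size=min_cluster_size, power=power)
    models = [
        calibrate_module(genes, logfc_train, module_id=f"M{i + 1:03d}")
        for i, genes in enumerate(clusters)
    ]
    return merge_modules(models, logfc_train, r_threshold=r_threshold)


def avg_abs_eg(scores: pd.DataFrame | pd.Series, models) -> pd.Series | float:
    """Average absolute eigengene score over *base* modules: the package's
    scalar measure of an experiment's overall transcriptional activity.
    Restricting to base modules avoids double-counting merged constituents."""
    base_ids = [m.module_id for m in models if m.is_base]
    if isinstance(scores, pd.Series):
        return float(scores.loc[base_ids].abs().mean())
    return scores.loc[base_ids].abs().mean(axis=0)


def preservation_z(
    model: ModuleModel,
    test_logfc: LogFCMatrix,
    n_random: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Simplified permutation preservation Z.

    Statistic: mean absolute pairwise correlation among member genes in the
    test data. Z-normalized against the same statistic on size-matched random
    gene selections from the test matrix. (A density-only simplification of
    the composite Z-summary used with full network toolkits.)
    """
    rng = rng or np.random.default_rng(0)
    genes = [g for g in model.gene_ids if g in test_logfc.frame.index]
    if len(genes) < 2:
        raise ValueError(f"{model.module_id}: fewer than 2 member genes in test data")

    def mean_abs_corr(gene_list) -> float:
        C = np.corrcoef(test_logfc.frame.loc[gene_list].to_numpy())
        iu = np.triu_indices_from(C, k=1)
        return float(np.abs(C[iu]).mean())

    observed = mean_abs_corr(genes)
    all_genes = np.asarray(test_logfc.genes)
    null = np.array([
        mean_abs_corr(rng.choice(all_genes, size=len(genes), replace=False))
        for _ in range(n_random)
    ])
    return float((observed - null.mean()) / null.std(ddof=1))


# ---------------------------------------------------------------------------
# serialization (TSV of members + JSON header per module set)


def save_modules(models, tsv_path, json_path) -> None:
    rows = []
    for m in models:
        for mem in m.members:
            rows.append((m.module_id, mem.gene_id, mem.loading, mem.train_mean, mem.train_sd))
    pd.DataFrame(rows, columns=["module", "gene", "loading", "train_mean", "train_sd"]).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.10g"
    )
    header = {
        m.module_id: {
            "raw_score_sd": m.raw_score_sd,
            "pc1_variance_fraction": m.pc1_variance_fraction,
            "kind": m.kind,
            "is_base": m.is_base,
            "constituents": m.constituents,
        }
        for m in models
    }
    with open(json_path, "w") as fh:
        json.dump(header, fh, indent=1)


def load_modules(tsv_path, json_path) -> list:
    table = pd.read_csv(tsv_path, sep="\t")
    with open(json_path) as fh:
        header = json.load(fh)
    models = []
    for module_id, grp in table.groupby("module", sort=False):
        meta = header[module_id]
        members = [
            ModuleMember(r.gene, float(r.loading), float(r.train_mean), float(r.train_sd))
            for r in grp.itertuples()
        ]
        models.append(ModuleModel(
            module_id=module_id, members=members,
            raw_score_sd=float(meta["raw_score_sd"]),
            pc1_variance_fraction=float(meta["pc1_variance_fraction"]),
            kind=meta["kind"], is_base=bool(meta["is_base"]),
            constituents=list(meta.get("constituents", [])),
        ))
    return models
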