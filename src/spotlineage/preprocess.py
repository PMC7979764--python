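"""QC filtering, normalization, HVG selection, PCA, and graph clustering.

The pipeline follows the standard single-cell recipe: drop cells with
fewer than 200 detected genes or more than 20% mitochondrial counts
(boundaries kept), library-size normalize to 1e6 and natural-log
transform, rank genes by vst standardized variance, reduce to 20 PCs on
scaled data, and cluster a Jaccard-weighted shared-nearest-neighbor graph
with Louvain modularity optimization. The same operations serve both
dissociated cells and spatial spots (spots: k=30, resolution=0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix

logger = logging.getLogger("spotlineage")


@dataclass
class QCConfig:
    min_genes: int = 200
    max_mito_frac: float = 0.20
    mito_gene_set: list[str] | None = None  # explicit gene names
    mito_prefix: str = "MT-"  # used when mito_gene_set is None

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must be in [0, 1]")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")

    def mito_mask(self, gene_names: list[str]) -> np.ndarray:
        if self.mito_gene_set is not None:
            s = set(self.mito_gene_set)
            return np.array([g in s for g in gene_names])
        return np.array([g.startswith(self.mito_prefix) for g in gene_names])


@dataclass
class NormalizationConfig:
    scale_factor: float = 1e6

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


@dataclass
class ReductionConfig:
    n_hvg: int = 2000
    hvg_method: str = "vst"
    n_pcs: int = 20
    knn_k: int = 30
    resolution: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k < 2:
            raise ValueError("knn_k must be >= 2")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_metrics(m: ExpressionMatrix, qc: QCConfig) -> pd.DataFrame:
    """Per-observation detected-gene counts and mitochondrial fraction."""
    counts = sp.csc_matrix(m.counts)
    detected = np.diff(counts.indptr)  # nonzero genes per column
    total = np.asarray(counts.sum(axis=0)).ravel()
    mito = qc.mito_mask(m.gene_names)
    mito_total = np.asarray(counts[mito].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"n_genes": detected, "total_counts": total, "mito_frac": mito_frac},
        index=pd.Index(m.obs_ids, name="barcode"),
    )


def filter_cells(m: ExpressionMatrix, qc: QCConfig | None = None) -> ExpressionMatrix:
    """Remove observations with < min_genes detected genes or > max_mito_frac.

    Boundaries are kept: a cell with exactly ``min_genes`` detected genes or
    exactly ``max_mito_frac`` mitochondrial fraction survives ("less than" /
    "more than" semantics). Idempotent.
    """
    qc = qc or QCConfig()
    metrics = qc_metrics(m, qc)
    keep = (metrics["n_genes"] >= qc.min_genes) & (
        metrics["mito_frac"] <= qc.max_mito_frac
    )
    n_kept = int(keep.sum())
    if "stage" in m.obs_meta.columns:
        for stage, grp in keep.groupby(m.obs_meta["stage"].to_numpy()):
            logger.info("QC %s: kept %d / %d", stage, int(grp.sum()), len(grp))
    logger.info("QC: kept %d / %d observations", n_kept, m.n_obs)
    if n_kept == 0:
        logger.warning("QC removed every observation")
    return m.subset_obs(keep.to_numpy())


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def lognormalize(
    m: ExpressionMatrix, n: NormalizationConfig | None = None
) -> sp.csr_matrix:
    """ln(count / obs_total * scale_factor + 1), sparsity preserved.

    Observations with zero total counts get all-zero columns (warned).
    """
    n = n or NormalizationConfig()
    counts = sp.csr_matrix(m.counts, dtype=np.float64)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("negative counts")
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        logger.warning("%d observations have zero total counts", int((totals == 0).sum()))
    safe = np.where(totals > 0, totals, 1.0)
    out = sp.csc_matrix(counts)
    scale = n.scale_factor / safe
    out.data = np.log1p(out.data * np.repeat(scale, np.diff(out.indptr)))
    return sp.csr_matrix(out)


# ---------------------------------------------------------------------------
# HVG (vst)
# ---------------------------------------------------------------------------


def vst_standardized_variance(counts: sp.spmatrix, loess_frac: float = 0.3) -> np.ndarray:
    """Per-gene standardized variance under the vst procedure.

    A trend of log10(variance) on log10(mean) of the *raw* counts is fit by
    lowess; counts are standardized per gene by the trend-predicted sd and
    clipped at sqrt(N); the variance of the clipped standardized counts is
    returned. Genes with zero variance get 0.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    counts = sp.csr_matrix(counts, dtype=np.float64)
    n = counts.shape[1]
    mean = np.asarray(counts.mean(axis=1)).ravel()
    sq = counts.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)

    ok = var > 0
    fitted_var = np.zeros_like(var)
    x = np.log10(mean[ok])
    y = np.log10(var[ok])
    # lowess returns values at the supplied x; request sorted-unique eval
    smoothed = lowess(y, x, frac=loess_frac, return_sorted=True)
    fitted_var[ok] = 10 ** np.interp(x, smoothed[:, 0], smoothed[:, 1])

    clip = np.sqrt(n)
    std_var = np.zeros(counts.shape[0])
    sd = np.sqrt(fitted_var)
    counts_csr = counts
    for g in np.flatnonzero(ok):
        row = counts_csr.getrow(g)
        vals = np.zeros(n)
        vals[row.indices] = row.data
        z = np.clip((vals - mean[g]) / sd[g], -clip, clip)
        std_var[g] = z.var(ddof=1)
    return std_var


def select_hvg(
    m: ExpressionMatrix, r: ReductionConfig | None = None
) -> np.ndarray:
    """Indices of the top ``n_hvg`` genes by vst standardized variance.

    Deterministic: ties broken by gene order after a stable sort on
    (-variance, index). If fewer genes have nonzero variance than
    requested, all of them are returned with a warning.
    """
    r = r or ReductionConfig()
    std_var = vst_standardized_variance(m.counts)
    ok = np.flatnonzero(std_var > 0)
    if ok.size < r.n_hvg:
        logger.warning(
            "only %d genes with nonzero variance (< n_hvg=%d); returning all",
            ok.size,
            r.n_hvg,
        )
        order = ok[np.argsort(-std_var[ok], kind="stable")]
        return order
    order = np.argsort(-std_var, kind="stable")
    return order[: r.n_hvg]


# ---------------------------------------------------------------------------
# scaling + PCA
# ---------------------------------------------------------------------------


def scale_genes(normalized: sp.spmatrix, clip: float = 10.0) -> np.ndarray:
    """Center and unit-variance scale each gene (row); clip at +-clip."""
    x = np.asarray(
        normalized.todense() if sp.issparse(normalized) else normalized, dtype=np.float64
    )
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return np.clip((x - mu) / sd, -clip, clip)


def run_pca(
    normalized_hvg: sp.spmatrix | np.ndarray, r: ReductionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of scaled genes x obs data -> (obs x n_pcs embedding, explained var).

    Components are ordered by decreasing explained variance with a
    deterministic sign convention (the largest-magnitude gene loading of
    each component is positive). If ``n_pcs`` exceeds the matrix rank the
    embedding is truncated with a warning.
    """
    r = r or ReductionConfig()
    x = scale_genes(normalized_hvg)  # genes x obs, centered before clipping
    n_obs = x.shape[1]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    k = min(r.n_pcs, rank)
    if k < r.n_pcs:
        logger.warning("requested %d PCs but rank is %d; truncating", r.n_pcs, rank)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention on loadings (rows of u)
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    u *= flip
    vt *= flip[:, None]
    embedding = vt.T * s  # obs x k
    explained_var = s**2 / max(n_obs - 1, 1)
    return embedding, explained_var


# ---------------------------------------------------------------------------
# SNN + Louvain clustering
# ---------------------------------------------------------------------------


def snn_graph(embedding: np.ndarray, k: int, prune: float = 1 / 15) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph in embedding space.

    Each observation's neighborhood is its k nearest neighbors (self
    included); edge weight between i and j is the Jaccard overlap of their
    neighborhoods, pruned below ``prune``.
    """
    n = embedding.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    # include self in the neighborhood, total size k_eff + 1
    hood = np.hstack([np.arange(n)[:, None], idx])
    rows = np.repeat(np.arange(n), hood.shape[1])
    adj = sp.csr_matrix(
        (np.ones(rows.size), (rows, hood.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # |N(i) & N(j)|
    shared = sp.coo_matrix(shared)
    ksz = hood.shape[1]
    jac = shared.data / (2 * ksz - shared.data)
    mask = (jac >= prune) & (shared.row != shared.col)
    out = sp.csr_matrix(
        (jac[mask], (shared.row[mask], shared.col[mask])), shape=(n, n)
    )
    return out


def cluster_obs(
    embedding: np.ndarray, r: ReductionConfig | None = None
) -> np.ndarray:
    """Louvain community labels on the SNN graph of the embedding.

    Labels are contiguous integers ordered by decreasing cluster size;
    observations disconnected from the graph each form their own cluster.
    Deterministic under a fixed ``r.seed``.
    """
    import networkx as nx

    r = r or ReductionConfig()
    n = embedding.shape[0]
    if n < r.knn_k + 1:
        logger.warning("fewer observations (%d) than knn_k+1; using k=%d", n, n - 1)
    g = snn_graph(embedding, min(r.knn_k, max(n - 1, 1)))
    graph = nx.from_scipy_sparse_array(g)
    isolated = [v for v in graph.nodes if graph.degree(v) == 0]
    if isolated:
        logger.info("%d isolated observations become singleton clusters", len(isolated))
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=r.resolution, seed=r.seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(n, dtype=int)
    for ci, comm in enumerate(communities):
        labels[list(comm)] = ci
    return labels


# ---------------------------------------------------------------------------
# DE + annotation
# ---------------------------------------------------------------------------


def wilcoxon_de(
    normalized: sp.spmatrix,
    group_mask: np.ndarray,
    gene_names: list[str],
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum per gene.

    Returns statistic, two-sided p, log2 fold change of mean normalized
    expression (group vs rest, pseudocount 1e-9), and adjusted p. Constant
    genes get p = 1.
    """
    from statsmodels.stats.multitest import multipletests

    x = np.asarray(
        normalized.todense() if sp.issparse(normalized) else normalized, dtype=np.float64
    )
    a = x[:, group_mask]
    b = x[:, ~group_mask]
    res = scipy.stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="auto")
    stat = np.atleast_1d(res.statistic).astype(float)
    p = np.atleast_1d(res.pvalue).astype(float)
    const = x.max(axis=1) == x.min(axis=1)
    p[const] = 1.0
    eps = 1e-9
    lfc = np.log2((a.mean(axis=1) + eps) / (b.mean(axis=1) + eps))
    if adjust == "bonferroni":
        p_adj = np.minimum(p * len(p), 1.0)
    else:
        p_adj = multipletests(p, method=adjust)[1]
    return pd.DataFrame(
        {
            "gene": gene_names,
            "statistic": stat,
            "p_value": p,
            "log2_fc": lfc,
            "p_adj": p_adj,
        }
    )


def annotate_clusters(
    normalized: sp.spmatrix,
    labels: np.ndarray,
    marker_panels: dict[str, list[str]],
    gene_names: list[str],
    adjust: str = "bonferroni",
) -> tuple[dict[int, str], pd.DataFrame]:
    """Assign each cluster the type whose marker panel scores highest.

    Panel score = mean scaled (z-scored per gene) expression of the panel's
    genes in the cluster. Ties break by the margin over the second-highest
    panel, then lexicographically. Also returns a per-cluster one-vs-rest
    Wilcoxon marker table. Panel genes absent from the matrix are skipped
    with a warning.
    """
    if not marker_panels or any(len(v) == 0 for v in marker_panels.values()):
        raise ValueError("marker panels must be non-empty")
    z = scale_genes(normalized)
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    panel_idx: dict[str, list[int]] = {}
    for t, genes in marker_panels.items():
        found = [name_to_idx[g] for g in genes if g in name_to_idx]
        missing = len(genes) - len(found)
        if missing:
            logger.warning("panel %s: %d genes absent, skipped", t, missing)
        panel_idx[t] = found

    mapping: dict[int, str] = {}
    tables = []
    for c in np.unique(labels):
        mask = labels == c
        scores = {
            t: (z[idx][:, mask].mean() if idx else -np.inf)
            for t, idx in panel_idx.items()
        }
        # round before sorting so float noise cannot break exact ties
        ordered = sorted(scores.items(), key=lambda kv: (-round(kv[1], 9), kv[0]))
        mapping[int(c)] = ordered[0][0]
        de = wilcoxon_de(normalized, mask, gene_names, adjust=adjust)
        de.insert(0, "cluster", int(c))
        tables.append(de)
    marker_table = pd.concat(tables, ignore_index=True)
    return mapping, marker_table
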