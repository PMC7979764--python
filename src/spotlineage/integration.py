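"""Anchor-based integration of a single-cell reference with spatial spots.

The method treats every spatial spot as a weighted mix of reference cell
types. It (1) embeds both datasets into a joint space via canonical
correlation analysis on their shared highly variable genes, (2) finds
mutual-nearest-neighbor *anchors* — (cell, spot) pairs that appear to
share a biological state — scored by neighborhood overlap and filtered
for consistency in gene space, and (3) transfers annotations across the
anchors with a Gaussian distance kernel: one-hot cell-type labels yield
per-spot *prediction scores* (rows sum to 1), and one-hot individual cell
identities yield the sparse spots x cells *similarity map* used later for
pseudotime projection. Collapsing the similarity map by cell type
reproduces the prediction scores exactly — the module's consistency
theorem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("spotlineage")


@dataclass
class AnchorSet:
    """MNN anchor pairs between a reference and a query dataset."""

    pairs: np.ndarray  # (n_anchors, 2): ref index, query index
    scores: np.ndarray  # in [0, 1]
    ref_embedding: np.ndarray  # ref obs x d, L2-normalized
    query_embedding: np.ndarray  # query obs x d, L2-normalized
    cca_dims: int = 0

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be (n, 2)")
        if len({tuple(p) for p in self.pairs}) != len(self.pairs):
            raise ValueError("duplicate anchor pairs")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("anchor scores must lie in [0, 1]")
        if not self.cca_dims:
            self.cca_dims = self.ref_embedding.shape[1]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PredictionScores:
    """Spots x cell-types weight matrix from label transfer."""

    matrix: pd.DataFrame  # rows sum to 1
    tie_flag: np.ndarray = None
    uniform_flag: np.ndarray = None

    def __post_init__(self) -> None:
        rows = self.matrix.to_numpy().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("prediction score rows must sum to 1")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("prediction scores must be non-negative")
        if self.tie_flag is None:
            m = self.matrix.to_numpy()
            top = m.max(axis=1, keepdims=True)
            self.tie_flag = (np.isclose(m, top).sum(axis=1) > 1)
        if self.uniform_flag is None:
            self.uniform_flag = np.zeros(len(self.matrix), dtype=bool)

    @property
    def type_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def max_label(self) -> pd.Series:
        m = self.matrix.to_numpy()
        top = m.max(axis=1, keepdims=True)
        cols = np.array(self.matrix.columns, dtype=object)
        # ties -> lexicographically smallest type
        labels = [
            min(cols[np.isclose(row, t).ravel()]) for row, t in zip(m, top)
        ]
        return pd.Series(labels, index=self.matrix.index, name="max_label")

    @property
    def max_score(self) -> pd.Series:
        return self.matrix.max(axis=1).rename("max_score")


@dataclass
class SimilarityMap:
    """Sparse spots x cells weights from transferring cell identities."""

    matrix: sp.csr_matrix
    spot_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("similarity weights must be non-negative")

    def support(self, spot: int) -> np.ndarray:
        """Cells with nonzero weight for the given spot index."""
        return self.matrix.indices[
            self.matrix.indptr[spot] : self.matrix.indptr[spot + 1]
        ]


# ---------------------------------------------------------------------------
# CCA embedding
# ---------------------------------------------------------------------------


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def cca_embed(
    ref: sp.spmatrix | np.ndarray,
    query: sp.spmatrix | np.ndarray,
    d: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint CCA embedding of two genes x obs matrices on shared genes.

    Both inputs must already be restricted to the same gene rows (the
    intersection of each dataset's HVGs). Genes are standardized within
    each dataset; the top-``d`` singular vectors of X'Y give the paired
    embeddings, L2-normalized per observation with a deterministic sign
    convention.

    Returns ``(ref_embedding, query_embedding, singular_values)``.
    """
    x = np.asarray(ref.todense() if sp.issparse(ref) else ref, dtype=np.float64)
    y = np.asarray(query.todense() if sp.issparse(query) else query, dtype=np.float64)
    if x.shape[0] != y.shape[0]:
        raise ValueError("ref and query must share the same gene rows")
    if x.shape[0] == 0:
        raise ValueError("empty shared gene set")
    d_eff = min(d, x.shape[1], y.shape[1], x.shape[0])
    if d_eff < d:
        logger.warning("reducing CCA dims from %d to %d (matrix limits)", d, d_eff)
    xs = _standardize_rows(x)
    ys = _standardize_rows(y)
    c = xs.T @ ys  # n_ref x n_query
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    u, s, v = u[:, :d_eff], s[:d_eff], vt[:d_eff].T
    joint = np.vstack([u, v])
    flip = np.sign(joint[np.argmax(np.abs(joint), axis=0), np.arange(d_eff)])
    flip[flip == 0] = 1.0
    u, v = u * flip, v * flip

    def l2norm(m: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(m, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return m / nrm

    return l2norm(u), l2norm(v), s


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def _knn_indices(data: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=min(k, data.shape[0])).fit(data)
    return nn.kneighbors(query, return_distance=False)


def find_anchors(
    ref_embedding: np.ndarray,
    query_embedding: np.ndarray,
    k_anchor: int = 5,
    k_filter: int | None = 200,
    k_score: int = 30,
    ref_genes: np.ndarray | None = None,
    query_genes: np.ndarray | None = None,
) -> AnchorSet:
    """Mutual-nearest-neighbor anchors in the joint CCA space.

    A (cell, spot) pair is an anchor when each lies among the other's
    ``k_anchor`` nearest neighbors across datasets. When gene-space
    matrices are supplied, anchors whose reference cell is not among the
    spot's ``k_filter`` nearest reference cells in (standardized) gene
    space are removed. Each surviving anchor is scored by the shared
    overlap of the two observations' ``k_score`` neighborhoods in the
    joint embedding, min-max rescaled with 1st/90th percentile capping.
    """
    n_ref, n_query = ref_embedding.shape[0], query_embedding.shape[0]
    if k_anchor > min(n_ref, n_query):
        raise ValueError("k_anchor exceeds dataset size")
    nn_rq = _knn_indices(query_embedding, ref_embedding, k_anchor)  # ref -> query
    nn_qr = _knn_indices(ref_embedding, query_embedding, k_anchor)  # query -> ref
    qr_sets = [set(row) for row in nn_qr]
    pairs = [
        (i, j)
        for i in range(n_ref)
        for j in nn_rq[i]
        if i in qr_sets[j]
    ]
    if not pairs:
        raise ValueError("no anchors found; increase k_anchor")
    pairs = np.array(sorted(pairs), dtype=int)

    if ref_genes is not None and query_genes is not None and k_filter:
        xraw = np.asarray(
            ref_genes.todense() if sp.issparse(ref_genes) else ref_genes,
            dtype=np.float64,
        )
        yraw = np.asarray(
            query_genes.todense() if sp.issparse(query_genes) else query_genes,
            dtype=np.float64,
        )
        # standardize the query with the *reference* gene statistics so a
        # query cloud concentrated on one state still lands on the matching
        # reference cells instead of being re-centred onto everything
        mu = xraw.mean(axis=1, keepdims=True)
        sd = xraw.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        xg = (xraw - mu) / sd
        yg = (yraw - mu) / sd
        kf = min(k_filter, n_ref)
        nn_gene = _knn_indices(xg.T, yg.T, kf)  # per spot: nearest ref cells
        gene_sets = [set(row) for row in nn_gene]
        keep = np.array([a in gene_sets[b] for a, b in pairs])
        n_removed = int((~keep).sum())
        if n_removed:
            logger.info("gene-space filter removed %d / %d anchors", n_removed, len(pairs))
        pairs = pairs[keep]
        if len(pairs) == 0:
            raise ValueError("all anchors removed by gene-space filter")

    # score: shared-neighbor overlap in the union embedding
    joint = np.vstack([ref_embedding, query_embedding])
    ks = min(k_score, joint.shape[0] - 1)
    nn_joint = _knn_indices(joint, joint, ks + 1)[:, 1:]  # drop self
    hoods = [set(row) for row in nn_joint]
    raw = np.array(
        [len(hoods[a] & hoods[n_ref + b]) / ks for a, b in pairs], dtype=float
    )
    q01, q90 = np.quantile(raw, [0.01, 0.90])
    if q90 > q01:
        scores = np.clip((raw - q01) / (q90 - q01), 0.0, 1.0)
    else:
        scores = np.ones_like(raw)
    return AnchorSet(
        pairs=pairs,
        scores=scores,
        ref_embedding=ref_embedding,
        query_embedding=query_embedding,
    )


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------


def _anchor_weights(
    anchors: AnchorSet, k_weight: int = 50, sd: float = 1.0
) -> sp.csr_matrix:
    """Row-normalized spots x anchors Gaussian kernel weight matrix.

    For each query spot: its ``k_weight`` nearest anchors (distance from
    the spot to each anchor's query-side embedding), Gaussian kernel with
    bandwidth ``sd``, multiplied by anchor scores, normalized to sum 1.
    Spots whose weights vanish fall back to uniform over their k nearest
    anchors (flagged upstream via zero rows before normalization).
    """
    anchor_pos = anchors.query_embedding[anchors.pairs[:, 1]]
    n_spots = anchors.query_embedding.shape[0]
    kw = min(k_weight, len(anchors))
    nn = NearestNeighbors(n_neighbors=kw).fit(anchor_pos)
    dist, idx = nn.kneighbors(anchors.query_embedding)
    # normalize by the k-th anchor distance so the kernel adapts to local
    # anchor density (raw CCA distances are far below sd for normalized
    # embeddings, which would flatten the kernel into uniform smoothing)
    scale = dist[:, -1:].copy()
    scale[scale == 0] = 1.0
    dist = dist / scale
    w = np.exp(-(dist**2) / (2 * sd**2)) * anchors.scores[idx]
    sums = w.sum(axis=1, keepdims=True)
    zero = sums.ravel() == 0
    if zero.any():
        logger.warning("%d spots have vanishing anchor weights; using uniform", int(zero.sum()))
        w[zero] = 1.0 / kw
        sums[zero] = 1.0
    w = w / sums
    rows = np.repeat(np.arange(n_spots), kw)
    mat = sp.csr_matrix(
        (w.ravel(), (rows, idx.ravel())), shape=(n_spots, len(anchors))
    )
    return mat, zero


def transfer_labels(
    anchors: AnchorSet,
    ref_labels: np.ndarray | pd.Series,
    spot_ids: list[str] | None = None,
    k_weight: int = 50,
    sd: float = 1.0,
) -> PredictionScores:
    """Transfer cell-type labels across anchors -> per-spot prediction scores.

    Each spot's score row is the anchor-weight-averaged one-hot label
    vector of the anchors' reference cells; rows sum to 1. Type columns are
    sorted lexicographically.
    """
    ref_labels = np.asarray(ref_labels, dtype=object)
    if pd.isna(ref_labels).any():
        raise ValueError("unknown (NaN) label in ref_labels")
    types = sorted(set(ref_labels))
    w, uniform = _anchor_weights(anchors, k_weight=k_weight, sd=sd)
    anchor_types = pd.Categorical(
        ref_labels[anchors.pairs[:, 0]], categories=types
    ).codes
    onehot = sp.csr_matrix(
        (np.ones(len(anchors)), (np.arange(len(anchors)), anchor_types)),
        shape=(len(anchors), len(types)),
    )
    scores = np.asarray((w @ onehot).todense())
    index = spot_ids if spot_ids is not None else list(range(scores.shape[0]))
    df = pd.DataFrame(scores, index=pd.Index(index, name="spot"), columns=types)
    return PredictionScores(matrix=df, uniform_flag=uniform)


def transfer_identity(
    anchors: AnchorSet,
    n_cells: int,
    cell_ids: list[str] | None = None,
    spot_ids: list[str] | None = None,
    k_weight: int = 50,
    sd: float = 1.0,
) -> SimilarityMap:
    """Transfer individual cell identities -> sparse spots x cells weights.

    Identical machinery to :func:`transfer_labels` with every reference
    cell as its own one-hot label, so collapsing columns by cell type
    reproduces the prediction scores exactly.
    """
    w, _ = _anchor_weights(anchors, k_weight=k_weight, sd=sd)
    onehot = sp.csr_matrix(
        (np.ones(len(anchors)), (np.arange(len(anchors)), anchors.pairs[:, 0])),
        shape=(len(anchors), n_cells),
    )
    mat = sp.csr_matrix(w @ onehot)
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n_cells)]
    if spot_ids is None:
        spot_ids = [str(i) for i in range(mat.shape[0])]
    return SimilarityMap(matrix=mat, spot_ids=list(spot_ids), cell_ids=list(cell_ids))


def collapse_similarity_by_type(
    sim: SimilarityMap, ref_labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Sum similarity-map columns by reference cell type (spots x types)."""
    ref_labels = np.asarray(ref_labels, dtype=object)
    types = sorted(set(ref_labels))
    codes = pd.Categorical(ref_labels, categories=types).codes
    agg = sp.csr_matrix(
        (np.ones(len(ref_labels)), (np.arange(len(ref_labels)), codes)),
        shape=(len(ref_labels), len(types)),
    )
    out = np.asarray((sim.matrix @ agg).todense())
    return pd.DataFrame(out, index=pd.Index(sim.spot_ids, name="spot"), columns=types)
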