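"""Diffusion-potential pseudotime and its projection onto tissue spots.

Lineage-subset cells are embedded with a diffusion-potential method in
the spirit of heat-diffusion affinity embeddings: an adaptive-bandwidth
alpha-decay kernel on kNN distances is symmetrized and row-normalized
into a diffusion operator, powered to a diffusion time chosen at the
knee of the von Neumann entropy, log-transformed into potential
coordinates, and reduced by classical MDS. The first embedding
coordinate serves as a developmental-time proxy ("pseudotime"),
sign-anchored so the earliest developmental stage has the smaller mean
and rescaled to [0, 1]. Spot pseudotime for a lineage is the average
pseudotime of the cells holding nonzero weight for that spot in the
cell-spot similarity map.

The spot-projection operation accepts any per-cell pseudotime vector, so
externally computed orderings can be plugged in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .integration import SimilarityMap

logger = logging.getLogger("spotlineage")


@dataclass
class Pseudotime:
    """Per-cell scalar developmental ordering in [0, 1]."""

    cell_values: np.ndarray
    raw_coordinate: np.ndarray
    flipped: bool
    lineage: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.cell_values).all():
            raise ValueError("pseudotime values must be finite")


@dataclass
class SpotPseudotime:
    """Per-spot projected pseudotime; undefined where support is empty."""

    spot_values: np.ndarray  # NaN where undefined
    n_support_cells: np.ndarray
    spot_ids: list[str]

    @property
    def defined(self) -> np.ndarray:
        return self.n_support_cells > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pseudotime": self.spot_values,
                "n_support_cells": self.n_support_cells,
            },
            index=pd.Index(self.spot_ids, name="spot"),
        )


# ---------------------------------------------------------------------------
# diffusion embedding
# ---------------------------------------------------------------------------


def diffusion_operator(
    embedding: np.ndarray, knn: int = 15, alpha: float = 10.0
) -> np.ndarray:
    """Row-stochastic diffusion operator from an alpha-decay kernel.

    Bandwidths adapt per cell to the distance of its ``knn``-th neighbor;
    the kernel ``exp(-(d/sigma)^alpha)`` is symmetrized by averaging the
    two directed versions and row-normalized.
    """
    n = embedding.shape[0]
    if knn >= n:
        raise ValueError("knn must be < number of cells")
    d = squareform(pdist(embedding))
    nn = NearestNeighbors(n_neighbors=knn + 1).fit(embedding)
    dist, _ = nn.kneighbors(embedding)
    sigma = dist[:, -1]
    sigma[sigma == 0] = np.min(sigma[sigma > 0]) if (sigma > 0).any() else 1.0
    with np.errstate(over="ignore"):
        k = 0.5 * (
            np.exp(-((d / sigma[:, None]) ** alpha))
            + np.exp(-((d / sigma[None, :]) ** alpha))
        )
    np.fill_diagonal(k, 1.0)
    return k / k.sum(axis=1, keepdims=True)


def von_neumann_entropy(p: np.ndarray, t_max: int = 100) -> np.ndarray:
    """Entropy of the diffusion spectrum at each power t = 1..t_max."""
    s = np.linalg.svd(p, compute_uv=False)
    s = s[s > 1e-12]
    ent = np.empty(t_max)
    log_s = np.log(s)
    for i, t in enumerate(range(1, t_max + 1)):
        # work in log space: s**t underflows for large t
        log_st = t * log_s
        log_st -= log_st.max()
        st = np.exp(log_st)
        q = st / st.sum()
        q = q[q > 0]
        ent[i] = float(-(q * np.log(q)).sum())
    return ent


def knee_point(entropy: np.ndarray) -> int:
    """Diffusion time at the entropy knee (maximum distance to the chord).

    The knee is the t whose (t, H(t)) point lies farthest below the line
    joining the first and last points of the entropy curve.
    """
    if len(entropy) < 3:
        return 1
    t = np.arange(1, len(entropy) + 1, dtype=float)
    x0, x1 = t[0], t[-1]
    y0, y1 = entropy[0], entropy[-1]
    # distance from each point to the chord (up to a constant factor)
    dist = np.abs((y1 - y0) * t - (x1 - x0) * entropy + x1 * y0 - y1 * x0)
    return int(t[np.argmax(dist)])


def diffusion_embedding(
    embedding: np.ndarray,
    knn: int = 15,
    n_components: int = 2,
    t: int | str = "auto",
    alpha: float = 10.0,
    eps: float = 1e-7,
    t_max: int = 100,
) -> np.ndarray:
    """Diffusion-potential coordinates (cells x n_components).

    ``t="auto"`` picks the diffusion time at the von Neumann entropy knee.
    Potential = -log(P^t + eps); coordinates come from classical MDS of
    potential distances with a deterministic sign convention. Fully
    deterministic (dense linear algebra, no random initialization).
    """
    p = diffusion_operator(embedding, knn=knn, alpha=alpha)
    if t == "auto":
        t = knee_point(von_neumann_entropy(p, t_max=t_max))
        # raise t until the powered operator exceeds the log floor
        # everywhere: otherwise potential distances between far cells
        # saturate at -log(eps) and the leading coordinate loses ordering
        pt = np.linalg.matrix_power(p, int(t))
        while pt.min() < eps and t < 1024:
            t = int(t * 2)
            pt = np.linalg.matrix_power(p, int(t))
        logger.info("auto diffusion time t=%d", t)
    else:
        pt = np.linalg.matrix_power(p, int(t))
    u = -np.log(pt + eps)
    dist = squareform(pdist(u))
    # classical (Torgerson) MDS
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    w_pos = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(w_pos)
    flip = np.sign(coords[np.argmax(np.abs(coords), axis=0), np.arange(coords.shape[1])])
    flip[flip == 0] = 1.0
    return coords * flip


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------


def extract_pseudotime(
    coords: np.ndarray,
    stage_labels: np.ndarray | pd.Series,
    stage_order: list[str] | None = None,
    lineage: str = "",
) -> Pseudotime:
    """First embedding coordinate as pseudotime, sign-anchored by stage.

    The sign is flipped when the earliest stage's mean exceeds the latest
    stage's mean, then the values are min-max rescaled to [0, 1]. Stage
    order defaults to the sorted unique labels; pass ``stage_order`` for
    non-lexicographic stage names (e.g. day4 < day10).
    """
    c1 = np.asarray(coords)[:, 0].astype(float)
    stages = np.asarray(stage_labels, dtype=object)
    present = pd.unique(stages)
    if stage_order is None:
        order = sorted(present, key=str)
    else:
        order = [s for s in stage_order if s in set(present)]
    if len(order) < 2:
        logger.warning("single stage present; returning unsigned pseudotime")
        flipped = False
    else:
        early, late = order[0], order[-1]
        flipped = c1[stages == early].mean() > c1[stages == late].mean()
        if flipped:
            c1 = -c1
    rng_ = c1.max() - c1.min()
    values = (c1 - c1.min()) / rng_ if rng_ > 0 else np.zeros_like(c1)
    return Pseudotime(
        cell_values=values, raw_coordinate=np.asarray(coords)[:, 0], flipped=bool(flipped), lineage=lineage
    )


def spot_pseudotime(
    sim: SimilarityMap,
    pt: Pseudotime | np.ndarray,
    lineage_cells: np.ndarray,
    weighted: bool = False,
) -> SpotPseudotime:
    """Project per-cell pseudotime onto spots via the similarity map.

    For each spot, the unweighted arithmetic mean of pseudotime over the
    lineage cells holding nonzero similarity weight for it (optionally a
    similarity-weighted mean). Spots with empty support are undefined.

    ``lineage_cells`` indexes columns of the similarity map; ``pt`` values
    must align with those same columns (one value per cell of the full
    reference, or a Pseudotime over the lineage subset in the order of
    ``lineage_cells``).
    """
    values = pt.cell_values if isinstance(pt, Pseudotime) else np.asarray(pt, float)
    lineage_cells = np.asarray(lineage_cells, dtype=int)
    sub = sp.csr_matrix(sim.matrix[:, lineage_cells])
    if len(values) == sim.matrix.shape[1]:
        values = values[lineage_cells]
    elif len(values) != len(lineage_cells):
        raise ValueError("pseudotime length matches neither all cells nor the lineage")
    if sub.nnz == 0:
        logger.error("lineage cells are disjoint from the similarity support")
    out = np.full(sub.shape[0], np.nan)
    n_support = np.zeros(sub.shape[0], dtype=int)
    for i in range(sub.shape[0]):
        lo, hi = sub.indptr[i], sub.indptr[i + 1]
        cols = sub.indices[lo:hi]
        if cols.size == 0:
            continue
        n_support[i] = cols.size
        if weighted:
            w = sub.data[lo:hi]
            out[i] = float(np.average(values[cols], weights=w))
        else:
            out[i] = float(values[cols].mean())
    return SpotPseudotime(
        spot_values=out, n_support_cells=n_support, spot_ids=list(sim.spot_ids)
    )


# ---------------------------------------------------------------------------
# pseudotime-correlated genes
# ---------------------------------------------------------------------------


def pseudotime_gene_trends(
    normalized: sp.spmatrix | np.ndarray,
    pt: Pseudotime | np.ndarray,
    gene_names: list[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of each gene with pseudotime, permutation p.

    p-values come from ``n_permutations`` seeded permutations of the
    pseudotime vector (two-sided, add-one correction), with
    Benjamini-Hochberg q-values. Constant genes are reported with rho = 0
    and a flag.
    """
    from scipy.stats import rankdata
    from statsmodels.stats.multitest import multipletests

    x = np.asarray(
        normalized.todense() if sp.issparse(normalized) else normalized, dtype=np.float64
    )
    values = pt.cell_values if isinstance(pt, Pseudotime) else np.asarray(pt, float)
    n = x.shape[1]
    if n < 10:
        raise ValueError("need >= 10 cells")
    gr = rankdata(x, axis=1)
    pr = rankdata(values)
    const = x.max(axis=1) == x.min(axis=1)

    def corr_with(r: np.ndarray) -> np.ndarray:
        rc = r - r.mean()
        gc = gr - gr.mean(axis=1, keepdims=True)
        denom = np.sqrt((gc**2).sum(axis=1) * (rc**2).sum())
        denom[denom == 0] = np.inf
        return (gc @ rc) / denom

    rho = corr_with(pr)
    rho[const] = 0.0
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[0])
    for _ in range(n_permutations):
        null = corr_with(rng.permutation(pr))
        exceed += np.abs(null) >= np.abs(rho)
    p = (1.0 + exceed) / (n_permutations + 1.0)
    p[const] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": gene_names,
            "spearman_rho": rho,
            "p_value": p,
            "q_value": q,
            "constant": const,
        }
    )
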