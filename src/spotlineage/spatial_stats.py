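"""Spot-level spatial statistics over cell-type prediction scores.

Given per-spot prediction scores (rows summing to 1), this module
computes: the max-score label map, per-spot cell-type heterogeneity
(number of types with score strictly above a threshold, default 5%), the
type x type colocalization/proximity matrix (pair counts restricted to
each spot's top-4 predicted types), per-region mean composition, and
region-restricted differential expression (one-vs-rest two-sided
Wilcoxon rank-sum).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .integration import PredictionScores
from .preprocess import wilcoxon_de

logger = logging.getLogger("spotlineage")


@dataclass
class ColocalizationMatrix:
    """Symmetric type x type pair-count matrix accumulated over spots."""

    counts: pd.DataFrame
    n_spots_used: int
    top_k: int = 4
    weighted: bool = False

    def __post_init__(self) -> None:
        v = self.counts.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("colocalization matrix must be symmetric")
        if np.diag(v).any():
            raise ValueError("colocalization diagonal must be zero")

    @property
    def normalized(self) -> pd.DataFrame:
        """Row-normalized copy (each type's pair profile sums to 1)."""
        v = self.counts.to_numpy(dtype=float)
        sums = v.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return pd.DataFrame(v / sums, index=self.counts.index, columns=self.counts.columns)


@dataclass
class DEConfig:
    lfc_threshold: float = 0.5
    p_threshold: float = 1e-5
    adjust: str = "bonferroni"

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------


def label_spots_max(scores: PredictionScores) -> pd.DataFrame:
    """Per-spot argmax label with tie flag (ties -> lexicographically first)."""
    return pd.DataFrame(
        {
            "label": scores.max_label,
            "score": scores.max_score,
            "tie": scores.tie_flag,
        }
    )


def heterogeneity(scores: PredictionScores, threshold: float = 0.05) -> pd.Series:
    """Number of cell types with prediction score strictly above threshold."""
    if threshold >= 1:
        raise ValueError("threshold must be < 1")
    m = scores.matrix.to_numpy()
    return pd.Series(
        (m > threshold).sum(axis=1), index=scores.matrix.index, name="heterogeneity"
    )


def _top_types(row: np.ndarray, names: np.ndarray, top_k: int) -> list[int]:
    """Indices of the top_k nonzero-score types (score desc, name asc)."""
    nz = np.flatnonzero(row > 0)
    order = sorted(nz, key=lambda i: (-row[i], names[i]))
    return order[:top_k]


def colocalization(
    scores: PredictionScores, top_k: int = 4, weighted: bool = False
) -> ColocalizationMatrix:
    """Pair-count colocalization over each spot's top-k predicted types.

    Every unordered pair among a spot's top-k nonzero-score types
    increments the symmetric matrix by 1 (or by the smaller of the pair's
    scores when ``weighted``). Spots with fewer than two nonzero types
    contribute nothing.
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    names = np.array(scores.matrix.columns, dtype=object)
    m = scores.matrix.to_numpy()
    acc = np.zeros((len(names), len(names)))
    used = 0
    skipped = 0
    for row in m:
        top = _top_types(row, names, top_k)
        if len(top) < 2:
            skipped += 1
            continue
        used += 1
        for a, b in itertools.combinations(top, 2):
            inc = min(row[a], row[b]) if weighted else 1.0
            acc[a, b] += inc
            acc[b, a] += inc
    if skipped:
        logger.info("%d spots with <2 nonzero types contributed nothing", skipped)
    df = pd.DataFrame(acc, index=names, columns=names)
    return ColocalizationMatrix(counts=df, n_spots_used=used, top_k=top_k, weighted=weighted)


def composition_by_region(
    scores: PredictionScores, region_labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-region arithmetic mean of prediction-score rows (rows sum to 1)."""
    regions = np.asarray(region_labels, dtype=object)
    if len(regions) != len(scores.matrix):
        raise ValueError("region labels must cover every spot")
    out = scores.matrix.groupby(regions).mean()
    out.index.name = "region"
    return out


def regional_markers(
    normalized: sp.spmatrix | np.ndarray,
    gene_names: list[str],
    region_labels: np.ndarray | pd.Series,
    de: DEConfig | None = None,
) -> pd.DataFrame:
    """One-vs-rest differential expression per region.

    For each region with >= 3 spots: two-sided Wilcoxon rank-sum per gene
    against all other spots, log2 fold change of mean normalized
    expression, adjusted p, and a significance flag (|log2 FC| above and
    adjusted p below the configured thresholds, enriched side only).
    """
    de = de or DEConfig()
    regions = np.asarray(region_labels, dtype=object)
    uniq = [r for r in pd.unique(regions) if (regions == r).sum() >= 3]
    if len(uniq) < 2:
        raise ValueError("need >= 2 regions with >= 3 spots each")
    tables = []
    for r in sorted(uniq, key=str):
        mask = regions == r
        tab = wilcoxon_de(normalized, mask, gene_names, adjust=de.adjust)
        tab.insert(0, "region", r)
        tab["significant"] = (tab["log2_fc"] > de.lfc_threshold) & (
            tab["p_adj"] < de.p_threshold
        )
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)
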