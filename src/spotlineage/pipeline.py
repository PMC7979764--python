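"""End-to-end orchestration of the synthetic study and its analysis.

Runs generator -> QC/normalization -> clustering/annotation -> anchor
integration -> spatial statistics -> trajectory projection, and collects
recovery metrics against the generator's ground truth. Both the CLI
``run-all`` subcommand and the reproduction script drive this function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats

from . import integration, preprocess, spatial_stats, synthetic, trajectory
from .io import ExpressionMatrix

logger = logging.getLogger("spotlineage")

# conventional single-cell defaults: cells k=20/res=0.8; spots k=30/res=0.5
CELL_REDUCTION = preprocess.ReductionConfig(knn_k=20, resolution=0.8)
SPOT_REDUCTION = preprocess.ReductionConfig(knn_k=30, resolution=0.5)


@dataclass
class PipelineResult:
    reference: ExpressionMatrix
    tissue: ExpressionMatrix
    truth: synthetic.TruthBundle
    cell_labels: np.ndarray  # annotated per-cell types (post-QC order)
    cell_clusters: np.ndarray
    scores: integration.PredictionScores
    similarity: integration.SimilarityMap
    heterogeneity: pd.Series
    colocalization: spatial_stats.ColocalizationMatrix
    composition: pd.DataFrame
    spot_pt: trajectory.SpotPseudotime | None
    pseudotime: trajectory.Pseudotime | None
    lineage_cells: np.ndarray
    metrics: dict[str, Any] = field(default_factory=dict)


def _subset_truth_cells(truth: synthetic.TruthBundle, idx: np.ndarray) -> synthetic.TruthBundle:
    return replace(
        truth,
        cell_ids=[truth.cell_ids[i] for i in idx],
        cell_type=truth.cell_type[idx],
        cell_latent_time=truth.cell_latent_time[idx],
        cell_stage=truth.cell_stage[idx],
        cell_qc_flag=truth.cell_qc_flag[idx],
    )


def run_pipeline(
    config: synthetic.TissueConfig | None = None,
    seed: int = 0,
    cca_dims: int = 20,
    lineage: str = "epicardial",
    compute_regional_markers: bool = False,
) -> PipelineResult:
    """Run the full analysis on a fresh synthetic study and score recovery."""
    config = config or synthetic.TissueConfig(seed=seed)
    if config.seed != seed:
        config = replace(config, seed=seed)

    # ---- simulate ---------------------------------------------------------
    reference, truth = synthetic.simulate_reference(config)
    tissue, truth = synthetic.simulate_tissue(config, reference, truth)

    # ---- preprocess cells -------------------------------------------------
    qc = preprocess.QCConfig()
    metrics_df = preprocess.qc_metrics(reference, qc)
    keep = (
        (metrics_df["n_genes"] >= qc.min_genes)
        & (metrics_df["mito_frac"] <= qc.max_mito_frac)
    ).to_numpy()
    kept_idx = np.flatnonzero(keep)
    cells = reference.subset_obs(kept_idx)
    truth_cells = _subset_truth_cells(truth, kept_idx)

    norm_cells = preprocess.lognormalize(cells)
    cell_red = replace(CELL_REDUCTION, seed=seed)
    hvg = preprocess.select_hvg(cells, cell_red)
    emb_cells, _ = preprocess.run_pca(norm_cells[hvg], cell_red)
    clusters = preprocess.cluster_obs(emb_cells, cell_red)
    mapping, _ = preprocess.annotate_clusters(
        norm_cells, clusters, truth.marker_panels, cells.gene_names
    )
    cell_labels = np.array([mapping[c] for c in clusters], dtype=object)

    # ---- preprocess spots -------------------------------------------------
    norm_spots = preprocess.lognormalize(tissue)

    # ---- integrate --------------------------------------------------------
    ref_emb, query_emb, _ = integration.cca_embed(
        norm_cells[hvg], norm_spots[hvg], d=cca_dims
    )
    anchors = integration.find_anchors(
        ref_emb,
        query_emb,
        ref_genes=norm_cells[hvg],
        query_genes=norm_spots[hvg],
    )
    scores = integration.transfer_labels(anchors, cell_labels, spot_ids=tissue.obs_ids)
    similarity = integration.transfer_identity(
        anchors, n_cells=cells.n_obs, cell_ids=cells.obs_ids, spot_ids=tissue.obs_ids
    )

    # ---- spatial statistics ----------------------------------------------
    het = spatial_stats.heterogeneity(scores)
    coloc = spatial_stats.colocalization(scores)
    comp = spatial_stats.composition_by_region(scores, truth.spot_layer)
    markers = None
    if compute_regional_markers:
        markers = spatial_stats.regional_markers(
            norm_spots, tissue.gene_names, truth.spot_layer
        )

    # ---- trajectory -------------------------------------------------------
    lineage_types = [t for t, l in config.type_lineages.items() if l == lineage]
    lin_idx = np.flatnonzero(np.isin(cell_labels, lineage_types))
    pt = spot_pt = None
    if lin_idx.size >= 30:
        lin_red = replace(CELL_REDUCTION, seed=seed)
        lin_cells = cells.subset_obs(lin_idx)
        norm_lin = preprocess.lognormalize(lin_cells)
        hvg_lin = preprocess.select_hvg(lin_cells, lin_red)
        emb_lin, _ = preprocess.run_pca(norm_lin[hvg_lin], lin_red)
        coords = trajectory.diffusion_embedding(
            emb_lin, knn=min(15, lin_idx.size - 1), n_components=2
        )
        pt = trajectory.extract_pseudotime(
            coords,
            truth_cells.cell_stage[lin_idx],
            stage_order=config.stage_names,
            lineage=lineage,
        )
        spot_pt = trajectory.spot_pseudotime(
            similarity, _expand(pt, lin_idx, cells.n_obs), lin_idx
        )
    else:
        logger.warning(
            "only %d cells annotated to the %s lineage; skipping trajectory",
            lin_idx.size,
            lineage,
        )

    # ---- recovery metrics -------------------------------------------------
    from sklearn.metrics import adjusted_rand_score

    metrics: dict[str, Any] = {}
    metrics["n_cells_kept"] = int(cells.n_obs)
    metrics["n_spots"] = int(tissue.n_obs)
    metrics["clustering_ari"] = float(
        adjusted_rand_score(truth_cells.cell_type, clusters)
    )
    metrics["label_accuracy_cells"] = float(
        (cell_labels == truth_cells.cell_type).mean()
    )

    true_comp = truth.spot_composition.loc[scores.matrix.index]
    pred = scores.matrix.reindex(columns=true_comp.columns).fillna(0.0)
    pearson = [
        scipy.stats.pearsonr(pred.iloc[i], true_comp.iloc[i]).statistic
        if pred.iloc[i].std() > 0 and true_comp.iloc[i].std() > 0
        else 0.0
        for i in range(len(pred))
    ]
    metrics["median_spot_composition_pearson"] = float(np.median(pearson))
    metrics["composition_mae_per_type"] = float(
        np.abs(pred.to_numpy() - true_comp.to_numpy()).mean()
    )
    true_dominant = true_comp.idxmax(axis=1)
    metrics["max_label_accuracy"] = float(
        (scores.max_label.to_numpy() == true_dominant.to_numpy()).mean()
    )
    metrics["median_heterogeneity"] = float(het.median())

    if spot_pt is not None:
        defined = spot_pt.defined
        if defined.sum() >= 3:
            rho = scipy.stats.spearmanr(
                spot_pt.spot_values[defined], truth.spot_mean_latent_time[defined]
            ).statistic
            metrics["spot_pseudotime_spearman"] = float(rho)
    if pt is not None:
        pt_rho = scipy.stats.spearmanr(
            pt.cell_values, truth_cells.cell_latent_time[lin_idx]
        ).statistic
        metrics["lineage_pseudotime_spearman"] = float(abs(pt_rho))

    result = PipelineResult(
        reference=cells,
        tissue=tissue,
        truth=truth,
        cell_labels=cell_labels,
        cell_clusters=clusters,
        scores=scores,
        similarity=similarity,
        heterogeneity=het,
        colocalization=coloc,
        composition=comp,
        spot_pt=spot_pt,
        pseudotime=pt,
        lineage_cells=lin_idx,
        metrics=metrics,
    )
    if markers is not None:
        result.metrics["n_significant_regional_markers"] = int(
            markers["significant"].sum()
        )
    return result


def _expand(pt: trajectory.Pseudotime, idx: np.ndarray, n: int) -> np.ndarray:
    """Scatter lineage pseudotime into a length-n vector (NaN elsewhere)."""
    out = np.full(n, np.nan)
    out[idx] = pt.cell_values
    return out
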