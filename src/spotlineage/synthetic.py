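"""Synthetic layered-tissue generator with full ground truth.

Emulates the statistical structure of a developing-heart study that pairs
dissociated single-cell transcriptomes with Visium-style spatial spots:

* ~8-15 cell types drawn from myocardial, endocardial, epicardial (and
  immune) lineages, each with a panel of elevated marker genes;
* a continuous differentiation latent time in [0, 1] per cell that shifts a
  per-lineage "maturity program" linearly on the log-mean scale, sampled in
  four developmental stages with shifting type proportions and latent-time
  windows;
* negative-binomial counts with lognormal library-size factors and
  mitochondrial genes flagged by an ``MT-`` name prefix;
* a square lattice of spots, each mixing the raw counts of 10-20 hidden
  constituent cells sampled according to a layered ventricular anatomy
  (epicardium at the tissue border, endocardium and valve at the centre),
  with latent time increasing from the outer to the inner layers.

Every hidden variable is returned in a :class:`TruthBundle` so downstream
stages have parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix, write_spot_geometry

logger = logging.getLogger("spotlineage")

DEFAULT_LAYERS = (
    "epicardium",
    "compact_myocardium",
    "trabecular_myocardium",
    "endocardium",
    "valve",
)

# (type name, lineage, latent-time centre); truncated to n_cell_types
_TYPE_TEMPLATE = [
    ("immature_cardiomyocyte", "myocardial", 0.20),
    ("mature_cardiomyocyte", "myocardial", 0.80),
    ("endocardial_early", "endocardial", 0.25),
    ("endocardial_mature", "endocardial", 0.75),
    ("epicardial_progenitor", "epicardial", 0.15),
    ("epi_mesenchymal", "epicardial", 0.45),
    ("fibroblast", "epicardial", 0.75),
    ("mural", "epicardial", 0.85),
    ("vascular_endothelial", "endocardial", 0.85),
    ("valve_fibroblast", "epicardial", 0.60),
    ("erythrocyte", "immune", 0.50),
    ("macrophage", "immune", 0.60),
    ("dendritic_cell", "immune", 0.55),
    ("tmsb4x_high", "epicardial", 0.50),
    ("quiescent_cardiomyocyte", "myocardial", 0.40),
]

# target latent time per layer: differentiation advances from the outer
# epicardial layer toward the inner trabecular/endocardial layers
_LAYER_LATENT_TARGET = {
    "epicardium": 0.15,
    "compact_myocardium": 0.45,
    "trabecular_myocardium": 0.65,
    "endocardium": 0.80,
    "valve": 0.55,
}


class ConfigurationError(ValueError):
    """Inconsistent generator configuration."""


@dataclass
class TissueConfig:
    """Parameters of the synthetic study.

    Defaults mirror Visium geometry (55 um spots at 110 um pitch mixing
    10-20 cells) and a modest desk-scale dataset (8 types, 1000 genes,
    2000 cells, 20x20 spot lattice).
    """

    n_stages: int = 4
    layers: tuple[str, ...] = DEFAULT_LAYERS
    grid_shape: tuple[int, int] = (20, 20)
    spot_diameter_um: float = 55.0
    spot_pitch_um: float = 110.0
    cells_per_spot_range: tuple[int, int] = (10, 20)
    n_cell_types: int = 8
    markers_per_type: int = 10
    n_genes: int = 1000
    n_cells: int = 2000
    mito_gene_fraction: float = 0.05
    nb_dispersion: float = 2.0
    library_size_lognormal: tuple[float, float] = (0.0, 0.3)
    batch_effect_sd: float = 0.0
    marker_log_fc: float = 3.0
    program_genes_per_lineage: int = 60
    program_log_slope: float = 2.5
    qc_violator_fraction: float = 0.0
    capture_rate: float = 1.0
    lineage_filter: str | None = None  # restrict types to one lineage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_spot_range[0] < 1:
            raise ConfigurationError("cells_per_spot_range lower bound must be >= 1")
        if self.cells_per_spot_range[0] > self.cells_per_spot_range[1]:
            raise ConfigurationError("cells_per_spot_range must be non-decreasing")
        if self.spot_pitch_um < self.spot_diameter_um:
            raise ConfigurationError("spot_pitch_um must be >= spot_diameter_um")
        n_avail = len(self._template)
        if not (1 <= self.n_cell_types <= n_avail):
            raise ConfigurationError(f"n_cell_types must be in [1, {n_avail}]")
        if self.n_genes < self.n_cell_types * self.markers_per_type:
            raise ConfigurationError(
                "n_genes must be >= n_cell_types * markers_per_type "
                f"({self.n_cell_types} * {self.markers_per_type})"
            )
        if not 0 <= self.mito_gene_fraction < 1:
            raise ConfigurationError("mito_gene_fraction must be in [0, 1)")
        if not 0 < self.capture_rate <= 1:
            raise ConfigurationError("capture_rate must be in (0, 1]")

    @property
    def _template(self) -> list[tuple[str, str, float]]:
        if self.lineage_filter is None:
            return _TYPE_TEMPLATE
        return [t for t in _TYPE_TEMPLATE if t[1] == self.lineage_filter]

    @property
    def type_names(self) -> list[str]:
        return [t[0] for t in self._template[: self.n_cell_types]]

    @property
    def type_lineages(self) -> dict[str, str]:
        return {t[0]: t[1] for t in self._template[: self.n_cell_types]}

    @property
    def type_latent_centers(self) -> dict[str, float]:
        return {t[0]: t[2] for t in self._template[: self.n_cell_types]}

    @property
    def stage_names(self) -> list[str]:
        if self.n_stages == 4:
            return ["day4", "day7", "day10", "day14"]
        return [f"stage{i}" for i in range(self.n_stages)]


@dataclass
class TruthBundle:
    """Hidden variables of a simulated study.

    Cell-level arrays are populated by :func:`simulate_reference`; spot-level
    arrays by :func:`simulate_tissue`.
    """

    cell_ids: list[str]
    cell_type: np.ndarray
    cell_latent_time: np.ndarray
    cell_stage: np.ndarray
    cell_qc_flag: np.ndarray
    marker_panels: dict[str, list[str]]
    type_names: list[str]
    type_lineages: dict[str, str]
    # completed by simulate_tissue
    spot_ids: list[str] = field(default_factory=list)
    spot_composition: pd.DataFrame | None = None
    spot_layer: np.ndarray | None = None
    spot_mean_latent_time: np.ndarray | None = None
    constituent_cells: list[np.ndarray] = field(default_factory=list)

    @property
    def completed(self) -> bool:
        return self.spot_composition is not None

    def lineage_cells(self, lineage: str) -> np.ndarray:
        """Indices of cells belonging to the given lineage."""
        types = [t for t, l in self.type_lineages.items() if l == lineage]
        return np.flatnonzero(np.isin(self.cell_type, types))


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------


@dataclass
class _GeneModel:
    gene_names: list[str]
    base_log: np.ndarray  # (g,)
    marker_boost: np.ndarray  # (g, n_types), natural-log scale
    program_slope: np.ndarray  # (g, n_types), natural-log slope vs latent
    marker_panels: dict[str, list[str]]
    mito_idx: np.ndarray


def _build_gene_model(config: TissueConfig, rng: np.random.Generator) -> _GeneModel:
    g = config.n_genes
    types = config.type_names
    lineages = config.type_lineages
    n_mito = int(round(g * config.mito_gene_fraction))

    names: list[str] = []
    for i in range(n_mito):
        names.append(f"MT-G{i + 1:03d}")
    for i in range(g - n_mito):
        names.append(f"G{i + 1:05d}")

    # baseline on the natural-log scale, calibrated so healthy cells detect
    # well over 200 genes at the default gene count; mito genes get an
    # elevated baseline for a realistic ~7-10% mitochondrial fraction
    base_log = rng.normal(np.log(0.8), 0.7, size=g)
    base_log[:n_mito] = rng.normal(np.log(0.8) + np.log(2.0), 0.3, size=n_mito)

    marker_boost = np.zeros((g, len(types)))
    panels: dict[str, list[str]] = {}
    cursor = n_mito
    for ti, t in enumerate(types):
        idx = np.arange(cursor, cursor + config.markers_per_type)
        # markers must fit among non-mito genes; config validated n_genes
        idx = idx[idx < g]
        marker_boost[idx, ti] = config.marker_log_fc
        panels[t] = [names[i] for i in idx]
        cursor += config.markers_per_type

    program_slope = np.zeros((g, len(types)))
    lineage_names = sorted(set(lineages.values()))
    for lin in lineage_names:
        n_prog = min(config.program_genes_per_lineage, g - cursor)
        if n_prog <= 0:
            break
        idx = np.arange(cursor, cursor + n_prog)
        cursor += n_prog
        slopes = np.where(
            np.arange(n_prog) % 2 == 0, config.program_log_slope, -config.program_log_slope
        )
        cols = [ti for ti, t in enumerate(types) if lineages[t] == lin]
        for c in cols:
            program_slope[idx, c] = slopes

    return _GeneModel(
        gene_names=names,
        base_log=base_log,
        marker_boost=marker_boost,
        program_slope=program_slope,
        marker_panels=panels,
        mito_idx=np.arange(n_mito),
    )


def expected_expression(config: TissueConfig, latent: float = None) -> pd.DataFrame:
    """Expected (noise-free) mean expression, genes x types.

    Evaluated at each type's latent-time centre unless ``latent`` fixes a
    common value; library-size factor is taken as 1. Used by tests that
    assert marker fidelity on expectations rather than samples.
    """
    rng = np.random.default_rng(config.seed)
    model = _build_gene_model(config, rng)
    centers = config.type_latent_centers
    cols = {}
    for ti, t in enumerate(config.type_names):
        z = centers[t] if latent is None else latent
        log_mu = (
            model.base_log
            + model.marker_boost[:, ti]
            + model.program_slope[:, ti] * (z - 0.5)
        )
        cols[t] = np.exp(log_mu)
    return pd.DataFrame(cols, index=model.gene_names)


# ---------------------------------------------------------------------------
# simulate_reference
# ---------------------------------------------------------------------------


def simulate_reference(config: TissueConfig) -> tuple[ExpressionMatrix, TruthBundle]:
    """Simulate a dissociated single-cell reference with ground truth.

    Cells are drawn per stage with stage-shifted type proportions and
    latent-time windows; counts are negative binomial around a type- and
    latent-time-dependent mean with lognormal library-size factors. A
    ``qc_violator_fraction`` of cells is deliberately corrupted (half with
    fewer than 200 detected genes, half with >20% mitochondrial counts) so
    QC filtering has an exact planted truth.
    """
    rng = np.random.default_rng(config.seed)
    model = _build_gene_model(config, rng)
    types = config.type_names
    centers = np.array([config.type_latent_centers[t] for t in types])
    n = config.n_cells
    n_stages = config.n_stages

    # per-stage draws with shifting type proportions and latent windows
    stage_of = np.repeat(np.arange(n_stages), np.diff(np.linspace(0, n, n_stages + 1).astype(int)))
    type_idx = np.empty(n, dtype=int)
    latent = np.empty(n)
    for s in range(n_stages):
        sel = np.flatnonzero(stage_of == s)
        stage_center = (s + 0.5) / n_stages
        w = np.exp(-((centers - stage_center) ** 2) / (2 * 0.25**2))
        w /= w.sum()
        type_idx[sel] = rng.choice(len(types), size=sel.size, p=w)
        mid = 0.5 * (centers[type_idx[sel]] + stage_center)
        latent[sel] = np.clip(rng.normal(mid, 0.08), 0.0, 1.0)

    # stage batch effect (off by default): per-stage per-gene log shift
    batch_shift = (
        rng.normal(0.0, config.batch_effect_sd, size=(n_stages, config.n_genes))
        if config.batch_effect_sd > 0
        else np.zeros((n_stages, config.n_genes))
    )

    log_mu = (
        model.base_log[:, None]
        + model.marker_boost[:, type_idx]
        + model.program_slope[:, type_idx] * (latent - 0.5)[None, :]
        + batch_shift[stage_of].T
    )
    mu_lib, sigma_lib = config.library_size_lognormal
    lib = rng.lognormal(mu_lib, sigma_lib, size=n)
    mu = np.exp(log_mu) * lib[None, :]

    if np.isinf(config.nb_dispersion):
        counts = rng.poisson(mu)
    else:
        theta = config.nb_dispersion
        counts = rng.negative_binomial(theta, theta / (theta + mu))

    # planted QC violators
    qc_flag = np.full(n, "none", dtype=object)
    n_viol = int(round(config.qc_violator_fraction * n))
    if n_viol:
        viol = rng.choice(n, size=n_viol, replace=False)
        low = viol[: n_viol // 2 + n_viol % 2]
        high = viol[n_viol // 2 + n_viol % 2 :]
        for c in low:
            keep = rng.choice(config.n_genes, size=120, replace=False)
            mask = np.zeros(config.n_genes, dtype=bool)
            mask[keep] = True
            counts[~mask, c] = 0
            qc_flag[c] = "low_genes"
        for c in high:
            mito = model.mito_idx
            rest = counts[:, c].sum() - counts[mito, c].sum()
            target = int(np.ceil(0.35 / 0.65 * max(rest, 1)))
            cur = counts[mito, c].sum()
            if cur == 0:
                counts[mito[0], c] = target
            else:
                f = max(target / cur, 1.0)
                counts[mito, c] = np.ceil(counts[mito, c] * f).astype(counts.dtype)
            qc_flag[c] = "high_mito"

    cell_ids = [f"CELL{i:05d}" for i in range(n)]
    stage_names = np.array(config.stage_names, dtype=object)
    obs_meta = pd.DataFrame(
        {"stage": stage_names[stage_of]}, index=pd.Index(cell_ids, name="barcode")
    )
    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"SYNG{i:05d}" for i in range(config.n_genes)],
        gene_names=model.gene_names,
        obs_ids=cell_ids,
        obs_meta=obs_meta,
        kind="cells",
    )
    truth = TruthBundle(
        cell_ids=cell_ids,
        cell_type=np.array(types, dtype=object)[type_idx],
        cell_latent_time=latent,
        cell_stage=stage_names[stage_of],
        cell_qc_flag=qc_flag,
        marker_panels=model.marker_panels,
        type_names=types,
        type_lineages=config.type_lineages,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# tissue layout
# ---------------------------------------------------------------------------


def build_layer_map(config: TissueConfig) -> np.ndarray:
    """Default layer assignment on the lattice: concentric depth bands.

    The outermost ring is always the first configured layer (epicardium);
    remaining layers split the interior depth range evenly, with the last
    layer (valve) occupying the lattice centre.
    """
    rows, cols = config.grid_shape
    layers = list(config.layers)
    i, j = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    depth = np.minimum.reduce([i, j, rows - 1 - i, cols - 1 - j])
    d_max = max(depth.max(), 1)
    out = np.empty((rows, cols), dtype=object)
    out[:] = layers[0]
    if len(layers) > 1:
        inner = depth > 0
        frac = (depth - 1) / max(d_max - 1, 1)
        band = np.minimum((frac * (len(layers) - 1)).astype(int), len(layers) - 2)
        inner_layers = np.array(layers[1:], dtype=object)
        out[inner] = inner_layers[band[inner]]
        out[depth == d_max] = layers[-1]
    return out


# per-layer lineage budgets: each anatomical compartment has a hallmark
# lineage (myocardium is mostly cardiomyocytes, the endocardial lining is
# endocardial, valves are fibroblast-like) with minority lineages present —
# including epicardial-derived mesenchyme migrating into the compact wall
_LAYER_LINEAGE_BUDGET = {
    "epicardium": {"epicardial": 0.85, "myocardial": 0.07, "endocardial": 0.08},
    "compact_myocardium": {"myocardial": 0.65, "epicardial": 0.20, "endocardial": 0.15},
    "trabecular_myocardium": {"myocardial": 0.60, "endocardial": 0.32, "epicardial": 0.08},
    "endocardium": {"endocardial": 0.75, "myocardial": 0.12, "epicardial": 0.13},
    "valve": {"epicardial": 0.60, "endocardial": 0.30, "myocardial": 0.10},
}


def default_layer_composition(config: TissueConfig) -> pd.DataFrame:
    """Layer -> type composition matrix (rows sum to 1).

    Each layer's probability mass is budgeted across lineages (hallmark
    lineage dominant) and distributed within a lineage by each type's
    latent-time affinity to the layer's maturation target, so compartments
    have a clearly dominant type with realistic minority mixing.
    """
    types = config.type_names
    lineages = config.type_lineages
    centers = config.type_latent_centers
    present = sorted(set(lineages.values()))
    rows = {}
    for layer in config.layers:
        target = _LAYER_LATENT_TARGET.get(layer, 0.5)
        budget = dict(_LAYER_LINEAGE_BUDGET.get(layer, {}))
        # lineages outside the budget (e.g. immune) share a small remainder
        others = [l for l in present if l not in budget]
        leftover = max(1.0 - sum(budget.get(l, 0.0) for l in present), 0.0)
        for l in others:
            budget[l] = leftover / len(others) if others else 0.0
        w = np.zeros(len(types))
        for lin in present:
            members = [ti for ti, t in enumerate(types) if lineages[t] == lin]
            if not members or budget.get(lin, 0.0) <= 0:
                continue
            if layer == "valve" and lin == "epicardial":
                # valve interstitial cells are fibroblastic
                aff = np.array(
                    [
                        {"valve_fibroblast": 1.0, "fibroblast": 0.8}.get(types[ti], 0.1)
                        for ti in members
                    ]
                )
            else:
                aff = np.array(
                    [
                        np.exp(-((centers[types[ti]] - target) ** 2) / (2 * 0.25**2))
                        for ti in members
                    ]
                )
            w[members] = budget[lin] * aff / aff.sum()
        rows[layer] = w / w.sum()
    return pd.DataFrame(rows, index=types).T


def simulate_tissue(
    config: TissueConfig,
    reference: ExpressionMatrix,
    truth: TruthBundle,
    layer_map: np.ndarray | None = None,
    layer_composition: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, TruthBundle]:
    """Simulate Visium-like spots by summing hidden constituent cells.

    Each lattice spot draws 10-20 constituent cells (types multinomial on
    its layer's composition row; within a type, cells weighted toward the
    layer's latent-time target so differentiation forms an outer-to-inner
    gradient). The spot count vector is the exact integer sum of its
    constituents' counts, optionally followed by binomial downsampling at
    ``config.capture_rate``.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    rows, cols = config.grid_shape
    if layer_map is None:
        layer_map = build_layer_map(config)
    layer_map = np.asarray(layer_map, dtype=object)
    if layer_map.shape != (rows, cols):
        raise ConfigurationError(
            f"layer map shape {layer_map.shape} != grid_shape {(rows, cols)}"
        )
    if layer_composition is None:
        layer_composition = default_layer_composition(config)
    comp = layer_composition.reindex(columns=truth.type_names).fillna(0.0)
    if not np.allclose(comp.sum(axis=1), 1.0):
        raise ConfigurationError("layer composition rows must sum to 1")

    types = truth.type_names
    cells_by_type = {t: np.flatnonzero(truth.cell_type == t) for t in types}
    # usable cells: exclude planted QC violators (their counts are corrupted)
    ok = truth.cell_qc_flag == "none"
    for t in types:
        good = cells_by_type[t][ok[cells_by_type[t]]]
        if good.size:
            cells_by_type[t] = good

    ref_counts = sp.csc_matrix(reference.counts)
    lo, hi = config.cells_per_spot_range
    n_spots = rows * cols

    spot_ids, layers_out, comp_rows, mean_latent, constituents = [], [], [], [], []
    spot_counts = np.zeros((config.n_genes, n_spots), dtype=np.int64)
    array_rows, array_cols = [], []
    k = 0
    for r in range(rows):
        for c in range(cols):
            layer = layer_map[r, c]
            if layer not in comp.index:
                raise ConfigurationError(f"layer {layer!r} missing from composition")
            p = comp.loc[layer].to_numpy()
            n_cells = int(rng.integers(lo, hi + 1))
            type_counts = rng.multinomial(n_cells, p)
            target = _LAYER_LATENT_TARGET.get(layer, 0.5)
            chosen: list[int] = []
            for ti, m in enumerate(type_counts):
                if m == 0:
                    continue
                pool = cells_by_type[types[ti]]
                if pool.size == 0:
                    pool = np.flatnonzero(ok) if ok.any() else np.arange(len(truth.cell_ids))
                w = np.exp(
                    -((truth.cell_latent_time[pool] - target) ** 2) / (2 * 0.15**2)
                )
                w = w / w.sum()
                chosen.extend(rng.choice(pool, size=m, replace=True, p=w))
            chosen = np.array(sorted(chosen), dtype=int)
            vec = np.asarray(ref_counts[:, chosen].sum(axis=1)).ravel()
            if config.capture_rate < 1.0:
                vec = rng.binomial(vec, config.capture_rate)
            spot_counts[:, k] = vec
            realized = np.bincount(
                [types.index(truth.cell_type[i]) for i in chosen], minlength=len(types)
            )
            comp_rows.append(realized / realized.sum())
            spot_ids.append(f"SPOT_r{r:03d}_c{c:03d}")
            layers_out.append(layer)
            mean_latent.append(truth.cell_latent_time[chosen].mean())
            constituents.append(chosen)
            array_rows.append(r)
            array_cols.append(c)
            k += 1

    obs_meta = pd.DataFrame(
        {
            "array_row": array_rows,
            "array_col": array_cols,
            "in_tissue": True,
            "layer": layers_out,
            "x_um": np.array(array_cols) * config.spot_pitch_um,
            "y_um": np.array(array_rows) * config.spot_pitch_um,
        },
        index=pd.Index(spot_ids, name="barcode"),
    )
    tissue = ExpressionMatrix(
        counts=sp.csr_matrix(spot_counts),
        gene_ids=reference.gene_ids,
        gene_names=reference.gene_names,
        obs_ids=spot_ids,
        obs_meta=obs_meta,
        kind="spots",
    )
    completed = replace(
        truth,
        spot_ids=spot_ids,
        spot_composition=pd.DataFrame(comp_rows, index=spot_ids, columns=types),
        spot_layer=np.array(layers_out, dtype=object),
        spot_mean_latent_time=np.array(mean_latent),
        constituent_cells=constituents,
    )
    return tissue, completed


# ---------------------------------------------------------------------------
# truth round-trip
# ---------------------------------------------------------------------------


def write_truth(truth: TruthBundle, dir: str | Path) -> None:
    """Write the truth bundle as plain CSV tables (lossless round-trip)."""
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "cell_id": truth.cell_ids,
            "cell_type": truth.cell_type,
            "latent_time": truth.cell_latent_time,
            "stage": truth.cell_stage,
            "qc_flag": truth.cell_qc_flag,
        }
    ).to_csv(dir / "cells.csv", index=False)
    pd.DataFrame(
        [(t, g) for t, genes in truth.marker_panels.items() for g in genes],
        columns=["cell_type", "gene"],
    ).to_csv(dir / "marker_panels.csv", index=False)
    pd.DataFrame(
        {
            "cell_type": truth.type_names,
            "lineage": [truth.type_lineages[t] for t in truth.type_names],
        }
    ).to_csv(dir / "type_lineages.csv", index=False)
    if truth.completed:
        pd.DataFrame(
            {
                "spot_id": truth.spot_ids,
                "layer": truth.spot_layer,
                "mean_latent_time": truth.spot_mean_latent_time,
                "constituent_cells": [
                    ";".join(map(str, c)) for c in truth.constituent_cells
                ],
            }
        ).to_csv(dir / "spots.csv", index=False)
        truth.spot_composition.rename_axis("spot_id").to_csv(dir / "composition.csv")
    else:
        pd.DataFrame(
            columns=["spot_id", "layer", "mean_latent_time", "constituent_cells"]
        ).to_csv(dir / "spots.csv", index=False)
        pd.DataFrame(columns=["spot_id", *truth.type_names]).to_csv(
            dir / "composition.csv", index=False
        )


def read_truth(dir: str | Path) -> TruthBundle:
    dir = Path(dir)
    cells = pd.read_csv(dir / "cells.csv")
    panels_df = pd.read_csv(dir / "marker_panels.csv")
    lineages_df = pd.read_csv(dir / "type_lineages.csv")
    panels = {
        t: g["gene"].tolist() for t, g in panels_df.groupby("cell_type", sort=False)
    }
    truth = TruthBundle(
        cell_ids=cells["cell_id"].astype(str).tolist(),
        cell_type=cells["cell_type"].to_numpy(dtype=object),
        cell_latent_time=cells["latent_time"].to_numpy(),
        cell_stage=cells["stage"].to_numpy(dtype=object),
        cell_qc_flag=cells["qc_flag"].to_numpy(dtype=object),
        marker_panels=panels,
        type_names=lineages_df["cell_type"].tolist(),
        type_lineages=dict(
            zip(lineages_df["cell_type"], lineages_df["lineage"], strict=True)
        ),
    )
    spots = pd.read_csv(dir / "spots.csv")
    if len(spots):
        comp = pd.read_csv(dir / "composition.csv", index_col=0)
        truth = replace(
            truth,
            spot_ids=spots["spot_id"].astype(str).tolist(),
            spot_layer=spots["layer"].to_numpy(dtype=object),
            spot_mean_latent_time=spots["mean_latent_time"].to_numpy(),
            constituent_cells=[
                np.array([int(x) for x in str(s).split(";") if x != ""], dtype=int)
                for s in spots["constituent_cells"]
            ],
            spot_composition=comp,
        )
    return truth


def write_dataset(
    reference: ExpressionMatrix,
    tissue: ExpressionMatrix,
    truth: TruthBundle,
    dir: str | Path,
    per_stage: bool = False,
) -> None:
    """Write the full synthetic study in 10x triplet layout plus truth CSVs."""
    from .io import write_10x_counts

    dir = Path(dir)
    write_10x_counts(reference, dir / "cells")
    write_10x_counts(tissue, dir / "spots")
    geom = tissue.obs_meta[["in_tissue", "array_row", "array_col"]].copy()
    write_spot_geometry(geom.reset_index(), dir / "spot_geometry.csv")
    write_truth(truth, dir / "truth")
    if per_stage:
        for stage in pd.unique(reference.obs_meta["stage"]):
            sel = (reference.obs_meta["stage"] == stage).to_numpy()
            write_10x_counts(reference.subset_obs(sel), dir / f"cells_{stage}")
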