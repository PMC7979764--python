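"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import spotlineage as sl
from spotlineage import integration as ig, preprocess as pp
from spotlineage.pipeline import CELL_REDUCTION


@pytest.fixture(scope="session")
def small_config() -> sl.TissueConfig:
    """Tiny study for fast structural tests (36 spots, 8 types)."""
    return sl.TissueConfig(
        n_cells=400,
        n_genes=300,
        markers_per_type=6,
        grid_shape=(6, 6),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    ref, truth = sl.simulate_reference(small_config)
    tissue, truth = sl.simulate_tissue(small_config, ref, truth)
    return ref, tissue, truth


@pytest.fixture(scope="session")
def medium_config() -> sl.TissueConfig:
    """500 cells x 200 spots: the integration-scale study."""
    return sl.TissueConfig(
        n_cells=500,
        n_genes=600,
        grid_shape=(20, 10),
        seed=7,
    )


@pytest.fixture(scope="session")
def medium_transfer(medium_config):
    """Full anchor transfer on the medium study (shared across tests)."""
    cfg = medium_config
    ref, truth = sl.simulate_reference(cfg)
    tissue, truth = sl.simulate_tissue(cfg, ref, truth)
    norm_cells = pp.lognormalize(ref)
    norm_spots = pp.lognormalize(tissue)
    red = replace(CELL_REDUCTION, seed=cfg.seed)
    hvg = pp.select_hvg(ref, red)
    ref_emb, query_emb, _ = ig.cca_embed(norm_cells[hvg], norm_spots[hvg], d=20)
    anchors = ig.find_anchors(
        ref_emb, query_emb, ref_genes=norm_cells[hvg], query_genes=norm_spots[hvg]
    )
    scores = ig.transfer_labels(anchors, truth.cell_type, spot_ids=tissue.obs_ids)
    sim = ig.transfer_identity(
        anchors, n_cells=ref.n_obs, cell_ids=ref.obs_ids, spot_ids=tissue.obs_ids
    )
    return ref, tissue, truth, anchors, scores, sim


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
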