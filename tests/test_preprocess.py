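"""QC, normalization, HVG, PCA, clustering, annotation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import spotlineage as sl
from spotlineage.io import ExpressionMatrix
from spotlineage.preprocess import (
    QCConfig,
    ReductionConfig,
    annotate_clusters,
    cluster_obs,
    filter_cells,
    lognormalize,
    qc_metrics,
    run_pca,
    scale_genes,
    select_hvg,
    snn_graph,
    vst_standardized_variance,
    wilcoxon_de,
)


def _matrix_from_dense(dense, gene_names=None, kind="cells"):
    dense = np.asarray(dense)
    g, n = dense.shape
    gene_names = gene_names or [f"G{i}" for i in range(g)]
    return ExpressionMatrix(
        counts=sp.csr_matrix(dense),
        gene_ids=gene_names,
        gene_names=gene_names,
        obs_ids=[f"C{i}" for i in range(n)],
        kind=kind,
    )


class TestFilterCells:
    def test_min_genes_boundary_is_strict_less_than(self):
        """A cell with exactly 200 detected genes is kept; 199 is removed."""
        n_genes = 250
        dense = np.zeros((n_genes, 2))
        dense[:199, 0] = 1  # 199 detected
        dense[:200, 1] = 1  # 200 detected
        m = _matrix_from_dense(dense)
        kept = filter_cells(m, QCConfig(min_genes=200, max_mito_frac=1.0))
        assert kept.obs_ids == ["C1"]

    def test_mito_boundary_is_strict_more_than(self):
        """Exactly 20% mitochondrial counts is kept; above is removed."""
        genes = ["MT-1"] + [f"G{i}" for i in range(4)]
        dense = np.array(
            [
                [20, 21],  # mito gene
                [20, 20],
                [20, 20],
                [20, 19],
                [20, 20],
            ]
        )
        m = _matrix_from_dense(dense, gene_names=genes)
        kept = filter_cells(m, QCConfig(min_genes=0, max_mito_frac=0.20))
        assert kept.obs_ids == ["C0"]

    def test_all_zero_matrix_keeps_nothing(self):
        m = _matrix_from_dense(np.zeros((250, 4)))
        kept = filter_cells(m, QCConfig())
        assert kept.n_obs == 0

    def test_idempotent(self):
        cfg = sl.TissueConfig(n_cells=200, qc_violator_fraction=0.1, seed=21)
        ref, _ = sl.simulate_reference(cfg)
        once = filter_cells(ref)
        twice = filter_cells(once)
        assert once == twice

    def test_planted_violators_match_brute_force_scan(self):
        """Kept set equals an independent per-cell dense recount."""
        cfg = sl.TissueConfig(n_cells=300, qc_violator_fraction=0.12, seed=22)
        ref, _ = sl.simulate_reference(cfg)
        qc = QCConfig()
        kept = filter_cells(ref, qc)
        dense = ref.counts.toarray()
        mito = np.array([g.startswith("MT-") for g in ref.gene_names])
        expected = []
        for i in range(ref.n_obs):
            col = dense[:, i]
            detected = int((col > 0).sum())
            total = col.sum()
            frac = col[mito].sum() / total if total else 0.0
            if detected >= 200 and frac <= 0.20:
                expected.append(ref.obs_ids[i])
        assert kept.obs_ids == expected


class TestLognormalize:
    def test_stated_formula_value(self):
        dense = np.zeros((3, 1))
        dense[0, 0] = 10
        dense[1, 0] = 9990
        m = _matrix_from_dense(dense)
        out = lognormalize(m).toarray()
        assert out[0, 0] == pytest.approx(np.log(1001), abs=1e-9)
        assert out[2, 0] == 0.0

    def test_sparsity_pattern_preserved(self, small_study):
        ref, _, _ = small_study
        out = lognormalize(ref)
        assert (out != 0).nnz == (ref.counts != 0).nnz

    def test_matches_dense_oracle(self, rng):
        dense = rng.integers(0, 20, size=(40, 15)).astype(float)
        m = _matrix_from_dense(dense)
        out = lognormalize(m).toarray()
        totals = dense.sum(axis=0)
        oracle = np.log1p(dense / totals * 1e6)
        assert np.abs(out - oracle).max() < 1e-12

    def test_pre_log_scaled_counts_sum_to_scale_factor(self, rng):
        dense = rng.integers(1, 30, size=(25, 10)).astype(float)
        totals = dense.sum(axis=0)
        scaled = dense / totals * 1e6
        assert np.allclose(scaled.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_observation_warned_not_fatal(self, caplog):
        dense = np.zeros((5, 2))
        dense[0, 0] = 3
        m = _matrix_from_dense(dense)
        out = lognormalize(m).toarray()
        assert (out[:, 1] == 0).all()


class TestSelectHVG:
    def test_planted_high_variance_gene_ranks_first(self, rng):
        n = 100
        dense = rng.poisson(5, size=(30, n)).astype(float)
        # same mean as its neighbours but far higher variance, so the
        # mean-variance trend cannot absorb it
        dense[7] = rng.choice([0.0, 10.0], size=n)
        m = _matrix_from_dense(dense)
        idx = select_hvg(m, ReductionConfig(n_hvg=5))
        assert idx[0] == 7

    def test_permutation_invariance(self, rng):
        dense = rng.negative_binomial(2, 0.3, size=(50, 80)).astype(float)
        m = _matrix_from_dense(dense)
        idx = select_hvg(m, ReductionConfig(n_hvg=10))
        perm = rng.permutation(50)
        m2 = _matrix_from_dense(dense[perm], gene_names=[f"G{p}" for p in perm])
        idx2 = select_hvg(m2, ReductionConfig(n_hvg=10))
        names1 = {m.gene_names[i] for i in idx}
        names2 = {m2.gene_names[i] for i in idx2}
        assert names1 == names2

    def test_matches_independent_vst_reimplementation(self, rng):
        """Loop-based dense reimplementation of the vst ranking as oracle."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        dense = rng.negative_binomial(2, 0.3, size=(60, 50)).astype(float)
        m = _matrix_from_dense(dense)
        k = 12
        idx = set(select_hvg(m, ReductionConfig(n_hvg=k)))

        n = dense.shape[1]
        mean = dense.mean(axis=1)
        var = dense.var(axis=1, ddof=1)
        ok = var > 0
        x, y = np.log10(mean[ok]), np.log10(var[ok])
        sm = lowess(y, x, frac=0.3, return_sorted=True)
        fit_sd = np.zeros(60)
        fit_sd[ok] = np.sqrt(10 ** np.interp(x, sm[:, 0], sm[:, 1]))
        std_var = np.zeros(60)
        clip = np.sqrt(n)
        for g in range(60):
            if not ok[g]:
                continue
            z = np.clip((dense[g] - mean[g]) / fit_sd[g], -clip, clip)
            std_var[g] = z.var(ddof=1)
        oracle = set(np.argsort(-std_var, kind="stable")[:k])
        assert idx == oracle

    def test_fewer_nonzero_variance_genes_returns_all(self):
        dense = np.ones((10, 20))
        dense[3] = np.arange(20)
        m = _matrix_from_dense(dense)
        idx = select_hvg(m, ReductionConfig(n_hvg=5))
        assert list(idx) == [3]


class TestPCA:
    def test_single_axis_of_variance(self, rng):
        z = rng.normal(size=50)
        dense = np.outer(np.ones(8), z) + rng.normal(0, 1e-9, (8, 50))
        emb, ev = run_pca(dense, ReductionConfig(n_pcs=3))
        assert ev[0] / ev.sum() > 0.999

    def test_matches_dense_eigensolver_oracle(self, rng):
        dense = rng.normal(size=(20, 10))
        emb, ev = run_pca(dense, ReductionConfig(n_pcs=4))
        x = scale_genes(dense)
        w, v = np.linalg.eigh(x @ x.T)  # gene-gene covariance (unnormalized)
        order = np.argsort(w)[::-1][:4]
        loadings = v[:, order]
        # subspace agreement: principal angles ~ 0
        emb_oracle = x.T @ loadings
        q1, _ = np.linalg.qr(emb)
        q2, _ = np.linalg.qr(emb_oracle)
        angles = np.linalg.svd(q1.T @ q2, compute_uv=False)
        assert np.abs(angles - 1).max() < 1e-8
        assert np.allclose(ev, w[order] / 9, rtol=1e-8)

    def test_explained_variance_nonincreasing(self, rng):
        dense = rng.normal(size=(30, 25))
        _, ev = run_pca(dense, ReductionConfig(n_pcs=10))
        assert (np.diff(ev) <= 1e-12).all()

    def test_rank_truncation_warns(self, rng, caplog):
        dense = rng.normal(size=(5, 4))
        emb, ev = run_pca(dense, ReductionConfig(n_pcs=10))
        assert emb.shape[1] <= 4


class TestClusterObs:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 1, size=(100, 3))
        b = rng.normal(0, 1, size=(100, 3)) + 30.0
        emb = np.vstack([a, b])
        labels = cluster_obs(emb, ReductionConfig(knn_k=15, resolution=0.5, seed=0))
        assert len(set(labels)) == 2
        assert len(set(labels[:100])) == 1 and len(set(labels[100:])) == 1

    def test_fixed_seed_reproducible(self, rng):
        emb = rng.normal(size=(150, 5))
        r = ReductionConfig(knn_k=10, resolution=0.8, seed=5)
        assert np.array_equal(cluster_obs(emb, r), cluster_obs(emb, r))

    def test_partition_beats_singletons_on_modularity(self, rng):
        import networkx as nx

        a = rng.normal(0, 1, size=(60, 3))
        b = rng.normal(0, 1, size=(60, 3)) + 10.0
        emb = np.vstack([a, b])
        r = ReductionConfig(knn_k=10, resolution=0.8, seed=1)
        labels = cluster_obs(emb, r)
        g = nx.from_scipy_sparse_array(snn_graph(emb, 10))
        parts = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        q = nx.community.modularity(g, parts, weight="weight")
        q_singleton = nx.community.modularity(
            g, [{i} for i in range(len(labels))], weight="weight"
        )
        assert q >= q_singleton

    def test_labels_ordered_by_size(self, rng):
        a = rng.normal(0, 1, size=(120, 3))
        b = rng.normal(0, 1, size=(40, 3)) + 25.0
        labels = cluster_obs(
            np.vstack([a, b]), ReductionConfig(knn_k=10, resolution=0.5, seed=0)
        )
        counts = np.bincount(labels)
        assert (np.diff(counts) <= 0).all()

    def test_recovers_planted_types_ari(self):
        """Clustering the synthetic reference recovers planted cell types."""
        from sklearn.metrics import adjusted_rand_score
        from spotlineage import preprocess as pp

        cfg = sl.TissueConfig(n_cells=800, n_genes=500, markers_per_type=8, seed=13)
        ref, truth = sl.simulate_reference(cfg)
        norm = pp.lognormalize(ref)
        red = ReductionConfig(n_hvg=500, knn_k=20, resolution=0.8, seed=13)
        hvg = select_hvg(ref, red)
        emb, _ = run_pca(norm[hvg], red)
        labels = cluster_obs(emb, red)
        assert adjusted_rand_score(truth.cell_type, labels) >= 0.9


class TestAnnotateClusters:
    def test_planted_markers_recover_truth_mapping(self, small_study):
        from spotlineage import preprocess as pp

        ref, _, truth = small_study
        norm = pp.lognormalize(ref)
        # use true types as "clusters" so the mapping is exactly identity
        codes, uniques = pd.factorize(truth.cell_type)
        mapping, table = annotate_clusters(
            norm, codes, truth.marker_panels, ref.gene_names
        )
        for c, t in mapping.items():
            assert t == uniques[c]

    def test_single_cluster_gets_best_panel(self, rng):
        # with one cluster spanning all cells, per-gene z-scores average to
        # zero in every panel, so the assignment falls to the deterministic
        # lexicographic tie rule
        dense = rng.poisson(3, size=(20, 30)).astype(float)
        panels = {"B": ["G1"], "A": ["G0"]}
        mapping, _ = annotate_clusters(
            sp.csr_matrix(dense), np.zeros(30, dtype=int), panels,
            [f"G{i}" for i in range(20)],
        )
        assert mapping[0] == "A"

    def test_planted_de_gene_has_positive_lfc(self, rng):
        dense = rng.poisson(2, size=(15, 40)).astype(float)
        group = np.zeros(40, dtype=bool)
        group[:20] = True
        dense[4, group] += 30
        table = wilcoxon_de(sp.csr_matrix(dense), group, [f"G{i}" for i in range(15)])
        assert table.loc[4, "log2_fc"] > 0
        assert table.loc[4, "p_adj"] < 0.01

    def test_missing_panel_gene_skipped(self, rng, caplog):
        dense = rng.poisson(3, size=(5, 20)).astype(float)
        panels = {"A": ["G0", "NOT_A_GENE"]}
        mapping, _ = annotate_clusters(
            sp.csr_matrix(dense), np.zeros(20, dtype=int), panels,
            [f"G{i}" for i in range(5)],
        )
        assert mapping[0] == "A"

    def test_empty_panel_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            annotate_clusters(
                sp.csr_matrix(np.ones((3, 4))), np.zeros(4, dtype=int),
                {"A": []}, ["G0", "G1", "G2"],
            )
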