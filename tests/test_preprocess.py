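"""QC, normalization, HVG, PCA, clustering and marker detection."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import cd4tex as ct
from cd4tex.preprocess import (
    Embedding,
    QCParams,
    cluster_cells,
    lognormalize,
    pca_embed,
    qc_filter,
    rank_markers,
    select_hvg,
)

from conftest import MITO_ONLY_QC, dense_norm


def _tiny_counts(values, symbols=None):
    values = np.asarray(values)
    n, g = values.shape
    return ct.CountMatrix(
        X=sp.csr_matrix(values), cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        gene_symbols=symbols or [f"G{j}" for j in range(g)],
    )


class TestQC:
    def test_planted_high_mito_cells_removed_exactly(self, small_sim):
        _, matrix, truth = small_sim
        filtered, qc = qc_filter(matrix, MITO_ONLY_QC)
        removed = qc.loc[~qc["kept"], "cell_id"].tolist()
        assert sorted(removed) == sorted(truth.high_mito_cells)

    def test_all_zero_cell_removed_by_min_genes(self):
        m = _tiny_counts([[0, 0, 0], [0, 2, 1]], symbols=["MT-X", "A", "B"])
        filtered, qc = qc_filter(m, QCParams(min_genes_per_cell=1, doublet_count_quantile=1.0))
        assert filtered.cell_ids == ["c1"]
        assert qc.loc[qc["cell_id"] == "c0", "mito_fraction"].item() == 0.0

    def test_identity_filter(self):
        m = _tiny_counts([[1, 2], [3, 4]])
        filtered, qc = qc_filter(m, QCParams(max_mito_fraction=1.0, min_genes_per_cell=0,
                                             doublet_count_quantile=1.0))
        assert filtered.n_cells == 2 and qc["kept"].all()

    def test_idempotent_with_absolute_threshold(self, small_sim):
        _, matrix, _ = small_sim
        params = QCParams(min_genes_per_cell=30, max_counts=700.0)
        once, qc1 = qc_filter(matrix, params)
        twice, qc2 = qc_filter(once, params)
        assert once.cell_ids == twice.cell_ids
        assert (once.X != twice.X).nnz == 0

    def test_zero_cells_retained_is_an_error(self):
        m = _tiny_counts([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="every cell"):
            qc_filter(m, QCParams(min_genes_per_cell=10))


class TestLognormalize:
    def test_closed_form(self):
        m = _tiny_counts([[10, 90]])
        nm = lognormalize(m)
        assert nm.X[0, 0] == pytest.approx(np.log(1001), abs=1e-10)
        assert nm.X[0, 1] == pytest.approx(np.log(9001), abs=1e-10)

    def test_zero_count_stays_zero(self):
        nm = lognormalize(_tiny_counts([[0, 5]]))
        assert nm.X[0, 0] == 0.0

    def test_depth_invariance(self):
        a = lognormalize(_tiny_counts([[3, 7, 10]]))
        b = lognormalize(_tiny_counts([[6, 14, 20]]))
        assert np.allclose(a.X.toarray(), b.X.toarray())

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            lognormalize(_tiny_counts([[0, 0]]))


class TestHVG:
    def test_n_equal_gene_count_returns_all(self, small_sim):
        _, matrix, _ = small_sim
        filtered, _ = qc_filter(matrix, MITO_ONLY_QC)
        hvg = select_hvg(filtered, n=filtered.n_genes)
        # zero-variance genes are excluded, everything else is returned
        assert len(hvg) <= filtered.n_genes
        assert len(set(hvg)) == len(hvg)

    def test_planted_variance_genes_rank_high(self):
        """Latent-factor genes carry extra variance and enter the HVG set."""
        cfg = ct.SimConfig(n_cells=3000, n_genes=10000, tex_fraction=0.5,
                           exhaustion_effect_delta=1.5, seed=7)
        matrix, truth = ct.simulate_counts(cfg)
        filtered, _ = qc_filter(matrix, MITO_ONLY_QC)
        hvg = set(select_hvg(filtered, n=2000))
        planted = set(truth.panel_membership["module1_exhaustion"])
        assert len(planted & hvg) >= 28


class TestPCA:
    def test_one_dimensional_data(self):
        t = np.linspace(0, 1, 50)
        X = np.outer(t, [1.0, 2.0, -1.0])
        nm = dense_norm(X)
        emb = pca_embed(nm, nm.gene_symbols, k=2)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_ratios_non_increasing(self, small_norm):
        nm = small_norm["norm"]
        hvg = nm.gene_symbols[:300]
        emb = pca_embed(nm, hvg, k=15)
        assert (np.diff(emb.explained_variance_ratio) <= 1e-12).all()


class TestClustering:
    def test_two_blobs_perfectly_separated(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.3, (100, 5)), rng.normal(8, 0.3, (100, 5))])
        emb = Embedding(coords=pts, explained_variance_ratio=np.ones(5) / 5)
        labels = cluster_cells(emb, n_neighbors=15, seed=0)
        truth = np.repeat([0, 1], 100)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_low_resolution_limit_single_cluster(self):
        rng = np.random.default_rng(1)
        emb = Embedding(coords=rng.normal(size=(120, 4)),
                        explained_variance_ratio=np.ones(4) / 4)
        labels = cluster_cells(emb, n_neighbors=15, resolution=1e-4, seed=0)
        assert len(set(labels)) == 1

    def test_planted_meta_clusters_recovered(self, small_norm):
        nm, meta = small_norm["norm"], small_norm["meta"]
        emb = pca_embed(nm, nm.gene_symbols, k=20)
        labels = cluster_cells(emb, n_neighbors=20, seed=0)
        assert adjusted_rand_score(meta, labels) >= 0.8


class TestMarkers:
    def test_exclusive_gene_is_significant(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(120, 30)).astype(float)
        X[:60, 0] += 5.0  # gene 0 expressed only above baseline in cluster 0
        nm = dense_norm(np.log1p(X))
        labels = np.repeat([0, 1], 60)
        res = rank_markers(nm, labels)
        row = res[(res["cluster"] == 0) & (res["gene"] == "G0000")].iloc[0]
        assert row["p_adj"] < 0.05 and row["significant"]

    def test_swapped_labels_flip_lfc_sign(self):
        rng = np.random.default_rng(1)
        nm = dense_norm(np.log1p(rng.poisson(2.0, size=(80, 20)).astype(float)))
        labels = np.repeat([0, 1], 40)
        a = rank_markers(nm, labels).set_index(["cluster", "gene"])
        b = rank_markers(nm, 1 - labels).set_index(["cluster", "gene"])
        # swapping labels relabels the clusters: new cluster 0 is the old
        # cluster 1, whose lfc is the exact negation of old cluster 0
        np.testing.assert_allclose(
            a.loc[0]["lfc"].to_numpy(),
            -b.loc[0].loc[a.loc[0].index, "lfc"].to_numpy(),
            atol=1e-12,
        )

    def test_foxp3_among_top_treg_markers(self, small_norm):
        nm, meta = small_norm["norm"], small_norm["meta"]
        code = {"Treg": 0, "Tfh": 1, "effector": 2, "naive": 3}
        labels = np.array([code[x] for x in meta])
        res = rank_markers(nm, labels)
        treg = res[(res["cluster"] == 0) & res["significant"]]
        top20 = treg.sort_values(["p_adj", "p", "gene"]).head(20)["gene"].tolist()
        assert "FOXP3" in top20

    def test_permutation_null_rejection_rate(self, small_norm):
        nm = small_norm["norm"]
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(10):
            labels = (rng.permutation(nm.n_cells) < nm.n_cells // 2).astype(int)
            res = rank_markers(nm, labels)
            sub = res[res["cluster"] == 0]
            fracs.append((sub["p"] < 0.05).mean())
        assert 0.02 < np.mean(fracs) < 0.08

    def test_tiny_cluster_skipped(self, small_norm):
        nm = small_norm["norm"]
        labels = np.zeros(nm.n_cells, dtype=int)
        labels[:2] = 1
        with pytest.warns(UserWarning, match="skipped"):
            res = rank_markers(nm, labels)
        assert set(res["cluster"]) == {0}
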