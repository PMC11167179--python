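"""Anchor panels, binned-background scores, Tex calls, score comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

import cd4tex as ct
from cd4tex.scoring import (
    GenePanel,
    classify_tex,
    compare_scores,
    derive_anchor_panel,
    fixed_panels,
    functional_scores,
    module_score,
)

from conftest import dense_norm


class TestDerivePanel:
    def test_duplicate_of_anchor_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 10))
        X[:, 3] = X[:, 0]  # gene 3 identical to the anchor gene 0
        nm = dense_norm(X)
        panel = derive_anchor_panel(nm, None, nm.gene_symbols[0], k=3)
        assert panel.genes[0] == nm.gene_symbols[3]
        assert nm.gene_symbols[0] not in panel.genes

    def test_zero_variance_anchor_rejected(self):
        nm = dense_norm(np.ones((10, 4)))
        with pytest.raises(ValueError, match="zero variance"):
            derive_anchor_panel(nm, None, nm.gene_symbols[0], k=2)

    def test_cell_order_invariance(self, small_norm):
        nm, meta = small_norm["norm"], small_norm["meta"]
        m1 = np.isin(meta, ("Tfh", "effector"))
        a = derive_anchor_panel(nm, m1, "PDCD1", k=20)
        perm = np.random.default_rng(3).permutation(nm.n_cells)
        nm_perm = nm.subset_cells(perm)
        b = derive_anchor_panel(nm_perm, m1[perm], "PDCD1", k=20)
        assert a.genes == b.genes

    def test_planted_partners_recovered(self, small_norm):
        nm, meta, truth = small_norm["norm"], small_norm["meta"], small_norm["truth"]
        m1 = np.isin(meta, ("Tfh", "effector"))
        panel = derive_anchor_panel(nm, m1, "PDCD1", k=30)
        planted = set(truth.panel_membership["module1_exhaustion"])
        assert len(planted & set(panel.genes)) >= 20  # strong effect, small n


class TestModuleScore:
    def test_self_control_gives_zero(self, small_norm):
        nm = small_norm["norm"]
        panel = fixed_panels()["suppressive"]
        score = module_score(nm, None, panel, control_genes=list(panel.genes))
        assert np.allclose(score.values, 0.0, atol=1e-12)

    def test_per_cell_constant_shift_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 60))
        nm_a = dense_norm(X)
        shifted = X + rng.normal(size=(50, 1))  # different constant per cell
        nm_b = dense_norm(shifted)
        panel = GenePanel("p", nm_a.gene_symbols[:5])
        a = module_score(nm_a, None, panel, n_bins=6, seed=1)
        b = module_score(nm_b, None, panel, n_bins=6, seed=1)
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_constant_matrix_scores_constant(self):
        """Every gene constant across cells -> identical score everywhere."""
        X = np.tile(np.linspace(0.5, 3.0, 40), (25, 1))
        nm = dense_norm(X)
        panel = GenePanel("p", nm.gene_symbols[:10])
        score = module_score(nm, None, panel, n_bins=5, seed=0)
        assert np.allclose(score.values, score.values[0], atol=1e-12)

    def test_planted_tex_score_higher(self, small_norm):
        nm, meta, tex = small_norm["norm"], small_norm["meta"], small_norm["tex"]
        m1 = np.isin(meta, ("Tfh", "effector"))
        panel = derive_anchor_panel(nm, m1, "PDCD1", k=30)
        score = module_score(nm, m1, panel, seed=0)
        flags = np.where(tex[m1], "Tex", "nonTex")
        h, p = compare_scores(score, flags)
        assert p < 0.05
        assert score.values[tex[m1]].mean() > score.values[~tex[m1]].mean()

    def test_agrees_with_independent_binned_background_scorer(self, small_norm):
        """Scores track scanpy's independently implemented binned-background
        gene scoring (same idea, different binning/sampling details)."""
        import anndata as ad
        import scanpy as sc

        nm = small_norm["norm"]
        adata = ad.AnnData(X=nm.X.copy())
        adata.var_names = nm.gene_symbols
        panel = fixed_panels()["suppressive"]
        sc.tl.score_genes(adata, panel.genes, ctrl_size=100, n_bins=24,
                          score_name="ref", random_state=0)
        ours = module_score(nm, None, panel, seed=0)
        r = np.corrcoef(ours.values, adata.obs["ref"].to_numpy())[0, 1]
        assert r > 0.95

    def test_deterministic_given_seed(self, small_norm):
        nm = small_norm["norm"]
        panel = fixed_panels()["effective"]
        a = module_score(nm, None, panel, seed=11)
        b = module_score(nm, None, panel, seed=11)
        assert np.array_equal(a.values, b.values)


class TestClassifyTex:
    def test_strict_mean_rule(self):
        score = ct.ScoreVector("s", ["a", "b", "c"], np.array([1.0, 2.0, 3.0]), 24, 100, 0)
        call = classify_tex(score)
        assert list(call.flags) == ["nonTex", "nonTex", "Tex"]
        assert call.threshold == 2.0

    def test_all_identical_scores_all_nontex(self):
        score = ct.ScoreVector("s", ["a", "b"], np.zeros(2), 24, 100, 0)
        with pytest.warns(UserWarning, match="identical"):
            call = classify_tex(score)
        assert set(call.flags) == {"nonTex"}

    def test_partition_property(self, small_norm):
        nm, meta = small_norm["norm"], small_norm["meta"]
        treg = meta == "Treg"
        panel = derive_anchor_panel(nm, treg, "TIGIT", k=30)
        call = classify_tex(module_score(nm, treg, panel, seed=0))
        assert len(call.flags) == int(treg.sum())
        assert ((call.flags == "Tex") | (call.flags == "nonTex")).all()


class TestFunctionalScores:
    def test_bidirectional_module_contrast(self, small_norm):
        nm, meta, tex = small_norm["norm"], small_norm["meta"], small_norm["tex"]
        treg = meta == "Treg"
        eff = meta == "effector"
        sup = module_score(nm, treg, fixed_panels()["suppressive"], seed=5)
        h, p = compare_scores(sup, np.where(tex[treg], "Tex", "nonTex"))
        assert p < 0.05
        assert sup.values[tex[treg]].mean() > sup.values[~tex[treg]].mean()
        effsc = module_score(nm, eff, fixed_panels()["effective"], seed=6)
        h2, p2 = compare_scores(effsc, np.where(tex[eff], "Tex", "nonTex"))
        assert p2 < 0.05
        assert effsc.values[tex[eff]].mean() > effsc.values[~tex[eff]].mean()

    def test_three_scores_emitted(self, small_norm):
        nm, meta = small_norm["norm"], small_norm["meta"]
        nonnaive = meta != "naive"
        out = functional_scores(nm, nonnaive, tfh_cells=(meta == "Tfh"), seed=0)
        assert set(out) == {"suppressive", "effective", "chemotaxis"}
        assert all(v.values.size == int(nonnaive.sum()) for v in out.values())


class TestCompareScores:
    def test_welch_closed_form(self):
        t, p = compare_scores(np.array([1.0, 2, 3, 4, 5, 6]),
                              np.array(["a"] * 3 + ["b"] * 3), test="welch_t")
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(0.021312, abs=1e-5)

    def test_identical_groups_boundary(self):
        h, p = compare_scores(np.array([1.0, 1, 1, 1]), np.array(["a", "a", "b", "b"]))
        assert h == 0.0 and p == 1.0

    def test_kruskal_p_uniform_under_permutation(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=200)
        pvals = []
        for _ in range(300):
            labels = rng.permutation(np.repeat(["a", "b"], 100))
            _, p = compare_scores(values, labels)
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_scores(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))
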