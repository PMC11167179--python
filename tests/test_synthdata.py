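"""Generator-level checks: planted structure, determinism, config validation."""

import numpy as np
import pandas as pd
import pytest

import cd4tex as ct
from cd4tex.preprocess import lognormalize, qc_filter
from cd4tex.synthdata import ArmEffect, simulate_invivo

from conftest import MITO_ONLY_QC


@pytest.mark.parametrize(
    "bad",
    [
        dict(meta_cluster_probs={"Treg": 0.5, "Tfh": 0.2, "effector": 0.2, "naive": 0.2}),
        dict(exhaustion_effect_delta=-0.5),
        dict(panel_size=0),
        dict(n_genes=50),  # cannot host markers + panels + mito genes
        dict(clone_geometric_p_tex=0.0),
        dict(tex_fraction=1.5),
        dict(nb_dispersion=0.0),
        dict(high_mito_cell_count=10, n_cells=5),
    ],
)
def test_invalid_configs_rejected(bad):
    cfg = ct.SimConfig(**bad)
    with pytest.raises(ValueError):
        cfg.validate()


def test_simulation_is_deterministic():
    cfg = ct.SimConfig(n_cells=150, n_genes=700, seed=42)
    m1, t1 = ct.simulate_counts(cfg)
    m2, t2 = ct.simulate_counts(ct.SimConfig(n_cells=150, n_genes=700, seed=42))
    assert (m1.X != m2.X).nnz == 0
    pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())
    c1 = ct.simulate_contigs(t1, cfg)
    c2 = ct.simulate_contigs(t2, cfg)
    pd.testing.assert_frame_equal(c1, c2)


def test_high_mito_tail_is_exact(small_sim):
    """Exactly the configured number of cells exceed 5% mito fraction."""
    cfg, matrix, truth = small_sim
    from cd4tex.preprocess import cell_qc_metrics

    qc = cell_qc_metrics(matrix)
    high = qc.loc[qc["mito_fraction"] > 0.05, "cell_id"].tolist()
    assert sorted(high) == sorted(truth.high_mito_cells)
    assert len(high) == cfg.high_mito_cell_count


def test_null_anchor_correlation_centered_at_zero():
    """With delta = 0 the anchor and planted partner genes are uncorrelated."""
    cfg = ct.SimConfig(n_cells=3000, n_genes=800, tex_fraction=0.5,
                       exhaustion_effect_delta=0.0, marker_genes_per_program=10, seed=5)
    m, truth = ct.simulate_counts(cfg)
    nm = lognormalize(qc_filter(m, MITO_ONLY_QC)[0])
    sym = nm.symbol_index()
    X = np.asarray(nm.X.todense())
    a = X[:, sym["PDCD1"]]
    ac = a - a.mean()
    idx = [sym[g] for g in truth.panel_membership["module1_exhaustion"]]
    Xc = X[:, idx] - X[:, idx].mean(axis=0)
    r = Xc.T @ ac / np.sqrt((Xc**2).sum(axis=0) * (ac**2).sum())
    assert abs(r.mean()) < 0.05


def test_planted_panel_genes_positively_correlated(small_norm):
    """With delta >= 1 every planted partner gene tracks its anchor within
    the factor's home population."""
    nm, meta, truth = small_norm["norm"], small_norm["meta"], small_norm["truth"]
    sym = nm.symbol_index()
    module1 = np.isin(meta, ("Tfh", "effector"))
    X = np.asarray(nm.X.todense())[module1]
    a = X[:, sym["PDCD1"]]
    ac = a - a.mean()
    idx = [sym[g] for g in truth.panel_membership["module1_exhaustion"]]
    Xc = X[:, idx] - X[:, idx].mean(axis=0)
    r = Xc.T @ ac / np.sqrt((Xc**2).sum(axis=0) * (ac**2).sum())
    assert (r > 0).all()


def test_gene_exchangeability_under_flat_null():
    """No markers, no exhaustion effect, flat baselines: per-gene mean counts
    agree with the common negative-binomial mean."""
    cfg = ct.SimConfig(
        n_cells=2000, n_genes=500, exhaustion_effect_delta=0.0, marker_effect=0.0,
        anchor_module_effect=0.0, baseline_log_sd=0.0,
        special_gene_mean=float(np.exp(ct.SimConfig().baseline_log_mean)),
        marker_genes_per_program=5, seed=9,
    )
    m, _ = ct.simulate_counts(cfg)
    nonmito = np.array([not s.startswith("MT-") for s in m.gene_symbols])
    X = np.asarray(m.X.todense())[:, nonmito].astype(float)
    gene_means = X.mean(axis=0)
    se = X.std(axis=0, ddof=1) / np.sqrt(X.shape[0])
    analytic = 0.2 * np.exp(cfg.libsize_log_sd**2 / 2)  # E[count] = mu * E[libsize]
    z = np.abs(gene_means - analytic) / se
    assert (z < 3).mean() > 0.98
    assert (z < 5).all()


def test_tex_clones_larger_than_nontex(small_sim):
    _, _, truth = small_sim
    df = truth.to_frame()
    sizes = df.groupby("clone_id").agg(size=("cell_id", "count"), tex=("tex", "first"))
    assert sizes.loc[sizes["tex"], "size"].mean() > sizes.loc[~sizes["tex"], "size"].mean()


def test_contig_table_structure(small_sim):
    cfg, _, truth = small_sim
    contigs = ct.simulate_contigs(truth, cfg)
    # one TRA + one TRB per cell
    assert len(contigs) == 2 * len(truth.cell_ids)
    per_bc = contigs.groupby("barcode")["chain"].apply(set)
    assert all(v == {"TRA", "TRB"} for v in per_bc)
    # cells sharing a clone share the full V(D)J/CDR3 tuple
    df = contigs.merge(truth.to_frame()[["cell_id", "clone_id"]],
                       left_on="barcode", right_on="cell_id")
    key_cols = ["v_gene", "d_gene", "j_gene", "cdr3"]
    n_variants = df.groupby(["clone_id", "chain"])[key_cols].nunique().max().max()
    assert n_variants == 1
    # a singleton clone's barcode appears in exactly 2 rows
    singles = truth.to_frame().groupby("clone_id").filter(lambda g: len(g) == 1)
    bc = singles["cell_id"].iloc[0]
    assert (contigs["barcode"] == bc).sum() == 2


def test_invivo_planted_negative_correlation():
    tables = simulate_invivo(n_mice_per_arm=8, seed=3, ratio_volume_corr=-0.9)
    from cd4tex.invivo import endpoint_volumes, ratio_volume_correlation

    vols = endpoint_volumes(tables.measurements)
    res = ratio_volume_correlation(tables.tex_ratios, vols)
    assert res.r < 0
    assert res.r_squared > 0.25
    assert res.significant


def test_invivo_null_tukey_rejects_at_alpha():
    """Identical arm effects: the family-wise Tukey rejection rate stays
    near the nominal level over repeated simulations."""
    from cd4tex.invivo import endpoint_volumes, tukey_compare

    flat = {arm: ArmEffect(volume_logmean=np.log(600.0), ratio_logmean=0.0)
            for arm in ("control", "aPD1", "aCTLA4")}
    rejections = 0
    n_reps = 150
    for rep in range(n_reps):
        tables = simulate_invivo(n_mice_per_arm=6, effect_profile=flat, seed=50_000 + rep)
        vols = endpoint_volumes(tables.measurements)
        tukey = tukey_compare(vols)
        rejections += int((tukey["p_adj"] < 0.05).any())
    rate = rejections / n_reps
    assert 0.0 <= rate < 0.11  # FWER ~ 0.05 with binomial noise at 150 reps
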