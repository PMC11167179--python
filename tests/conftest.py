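import numpy as np
import pytest
import scipy.sparse as sp

import cd4tex as ct
from cd4tex.preprocess import QCParams, lognormalize, qc_filter

# QC settings that isolate the mitochondrial rule (no doublet/min-gene
# interference) for planted-truth work on small simulations
MITO_ONLY_QC = QCParams(min_genes_per_cell=30, doublet_count_quantile=1.0)


@pytest.fixture(scope="session")
def small_sim():
    """600-cell / 1200-gene simulation with strong exhaustion effect."""
    cfg = ct.SimConfig(n_cells=600, n_genes=1200, tex_fraction=0.5,
                       exhaustion_effect_delta=1.5, seed=7)
    matrix, truth = ct.simulate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    """QC'd + log-normalized view of small_sim plus aligned truth arrays."""
    _, matrix, truth = small_sim
    filtered, qc = qc_filter(matrix, MITO_ONLY_QC)
    nm = lognormalize(filtered)
    keep = qc["kept"].to_numpy()
    return {
        "norm": nm,
        "meta": truth.cell_meta_cluster[keep],
        "tex": truth.cell_tex[keep],
        "truth": truth,
        "kept": keep,
    }


def dense_norm(values, cell_prefix="c", gene_prefix="g"):
    """Build a NormMatrix from a dense array (test helper)."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ct.NormMatrix(
        X=sp.csr_matrix(values),
        cell_ids=[f"{cell_prefix}{i}" for i in range(n)],
        gene_ids=[f"{gene_prefix}{j:04d}" for j in range(g)],
        gene_symbols=[f"{gene_prefix.upper()}{j:04d}" for j in range(g)],
    )
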