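"""Cell-level QC, normalization, variable genes, embedding, clustering and
cluster marker detection.

The stages follow the standard Seurat-style single-cell workflow: remove
cells with > 5% mitochondrial counts (plus empty-droplet and doublet
heuristics), log-normalize to 10k counts per cell, select highly variable
genes by standardized variance, embed with PCA, cluster with Leiden on a
shared-nearest-neighbor graph, and rank cluster markers with a tie-corrected
Wilcoxon rank-sum test under Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_10x import CountMatrix, NormMatrix
from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


@dataclass
class QCParams:
    """Cell-filtering thresholds.

    ``doublet_count_quantile`` trims cells above that quantile of total
    counts (a transparent stand-in for a doublet caller); set to 1.0 to
    disable. ``max_counts`` overrides the quantile with an absolute cutoff,
    which makes the filter idempotent.
    """

    max_mito_fraction: float = 0.05
    min_genes_per_cell: int = 200
    doublet_count_quantile: float = 0.99
    max_counts: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in (0, 1]")
        if not 0.0 < self.doublet_count_quantile <= 1.0:
            raise ValueError("doublet_count_quantile must lie in (0, 1]")


def cell_qc_metrics(m: CountMatrix) -> pd.DataFrame:
    """Per-cell n_counts, n_genes and mitochondrial fraction (``MT-`` genes)."""
    X = m.X.tocsr()
    n_counts = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_cols = np.array([s.startswith(MITO_PREFIX) for s in m.gene_symbols])
    mito_counts = (
        np.asarray(X[:, mito_cols].sum(axis=1)).ravel() if mito_cols.any() else np.zeros(m.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_counts > 0, mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "n_counts": n_counts.astype(int),
            "n_genes": n_genes.astype(int),
            "mito_fraction": mito_fraction,
        }
    )


def qc_filter(m: CountMatrix, params: QCParams | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Filter cells; returns the retained matrix plus a per-cell QC table
    covering *all* input cells with a ``kept`` flag.

    A cell is kept when mito_fraction <= max_mito_fraction, n_genes >=
    min_genes_per_cell and n_counts does not exceed the doublet cutoff
    (``max_counts`` if given, else the ``doublet_count_quantile`` of the
    input's total-count distribution).
    """
    params = params or QCParams()
    qc = cell_qc_metrics(m)
    if params.max_counts is not None:
        cutoff = float(params.max_counts)
    elif params.doublet_count_quantile >= 1.0:
        cutoff = float(qc["n_counts"].max()) if len(qc) else 0.0
    else:
        cutoff = float(np.quantile(qc["n_counts"], params.doublet_count_quantile))
    kept = (
        (qc["mito_fraction"] <= params.max_mito_fraction)
        & (qc["n_genes"] >= params.min_genes_per_cell)
        & (qc["n_counts"] <= cutoff)
    )
    qc["kept"] = kept.to_numpy()
    n_kept = int(kept.sum())
    if n_kept == 0:
        raise ValueError(
            "QC removed every cell "
            f"(mito<=({params.max_mito_fraction}), min_genes={params.min_genes_per_cell}, "
            f"count cutoff={cutoff}); check thresholds against the input"
        )
    logger.info("qc_filter: kept %d / %d cells (count cutoff %.1f)", n_kept, m.n_cells, cutoff)
    idx = np.flatnonzero(kept.to_numpy())
    filtered = CountMatrix(
        X=m.X[idx],
        cell_ids=[m.cell_ids[i] for i in idx],
        gene_ids=list(m.gene_ids),
        gene_symbols=list(m.gene_symbols),
    )
    return filtered, qc


def lognormalize(m: CountMatrix, scale: float = 1e4) -> NormMatrix:
    """Per-cell depth normalization: ln(1 + scale * count / cell_total)."""
    X = m.X.tocsr().astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("lognormalize requires no all-zero cells (run QC first)")
    inv = sp.diags(scale / totals)
    X = inv @ X
    X.data = np.log1p(X.data)
    return NormMatrix(X=X, cell_ids=list(m.cell_ids), gene_ids=list(m.gene_ids),
                      gene_symbols=list(m.gene_symbols))


def _clipped_standardized_variance(X: sp.csc_matrix, mean: np.ndarray, exp_sd: np.ndarray) -> np.ndarray:
    """Variance of clip-at-sqrt(N) standardized counts, per gene.

    Zeros contribute (-mean/sd)^2; the clip applies to the upper tail only,
    as in variance-stabilizing HVG selection.
    """
    n = X.shape[0]
    clip = np.sqrt(n)
    out = np.zeros(X.shape[1])
    indptr = X.indptr
    data = X.data
    for j in range(X.shape[1]):
        if exp_sd[j] == 0:
            continue
        v = data[indptr[j] : indptr[j + 1]]
        z = np.minimum((v - mean[j]) / exp_sd[j], clip)
        z0 = -mean[j] / exp_sd[j]
        k = v.size
        out[j] = (np.sum(z**2) + (n - k) * z0**2) / (n - 1)
    return out


def select_hvg(m: CountMatrix, n: int = 2000) -> list[str]:
    """Select the ``n`` most variable genes by standardized variance.

    Per-gene mean and variance are taken on raw counts; expected variance is
    a degree-2 polynomial fit of log10(variance) on log10(mean); counts are
    standardized with the fitted sd, clipped at sqrt(n_cells), and genes are
    ranked by the variance of the clipped values (ties broken by gene id).
    Returns gene symbols, highest standardized variance first.
    """
    X = m.X.tocsc().astype(np.float64)
    n_cells = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n_cells / max(n_cells - 1, 1)
    nonzero = var > 0
    if nonzero.sum() < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    lx, ly = np.log10(mean[nonzero]), np.log10(var[nonzero])
    coeffs = np.polyfit(lx, ly, deg=2)
    exp_sd = np.zeros_like(var)
    exp_sd[nonzero] = np.sqrt(10.0 ** np.polyval(coeffs, lx))
    std_var = _clipped_standardized_variance(X, mean, exp_sd)
    std_var[~nonzero] = -np.inf
    n_eligible = int(nonzero.sum())
    if n_eligible < n:
        warnings.warn(
            f"only {n_eligible} genes have nonzero variance; returning all of them"
        )
        n = n_eligible
    order = np.lexsort((np.asarray(m.gene_ids, dtype=object), -std_var))
    return [m.gene_symbols[i] for i in order[:n]]


@dataclass
class Embedding:
    """PCA cell embedding: coordinates plus explained-variance ratios."""

    coords: np.ndarray
    explained_variance_ratio: np.ndarray
    genes: list[str] = field(default_factory=list)


def pca_embed(nm: NormMatrix, genes: list[str], k: int = 20, clip: float = 10.0) -> Embedding:
    """PCA on the HVG-restricted, per-gene standardized (clipped at +-clip)
    log-normalized matrix; components ordered by decreasing variance."""
    sym = nm.symbol_index()
    cols = [sym[g] for g in genes if g in sym]
    if not cols:
        raise ValueError("none of the requested genes are present")
    X = np.asarray(nm.X[:, cols].todense())
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -clip, clip)
    k_max = min(X.shape)
    if k > k_max:
        warnings.warn(f"requested {k} components but rank allows only {k_max}")
        k = k_max
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    coords = pca.fit_transform(X)
    return Embedding(coords=coords, explained_variance_ratio=pca.explained_variance_ratio_,
                     genes=[nm.gene_symbols[c] for c in cols])


def snn_graph(coords: np.ndarray, n_neighbors: int = 20, prune: float = 1 / 15) -> ig.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets (self
    included), edges below ``prune`` dropped."""
    n = coords.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix((np.ones(rows.size), (rows, idx.ravel())), shape=(n, n))
    shared = adj @ adj.T
    shared = sp.triu(shared.tocoo(), k=1).tocoo()
    union = 2 * (k + 1) - shared.data
    jac = shared.data / union
    keep = jac >= prune
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_cells(
    e: Embedding, n_neighbors: int = 20, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on the SNN graph; labels are consecutive
    integers ordered by descending cluster size."""
    if e.coords.shape[0] < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 cells")
    g = snn_graph(e.coords, n_neighbors=n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # relabel by descending size, ties by original label for determinism
    sizes = pd.Series(labels).value_counts().sort_values(ascending=False)
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], dtype=int)


def _tie_term(column: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values in one gene column."""
    _, counts = np.unique(column, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def rank_markers(
    nm: NormMatrix,
    labels: np.ndarray,
    alpha: float = 0.05,
    lfc_threshold: float = 0.25,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum (normal approximation, tie-corrected) of
    each gene, cluster vs rest, with BH adjustment within each cluster.

    Returns one row per (cluster, gene) with z statistic, lfc
    (ln of expm1-mean pseudocounted ratio), raw and adjusted p, and a
    ``significant`` flag at adjusted p < alpha and lfc > lfc_threshold.
    """
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels).tolist())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    X = np.asarray(nm.X.todense())
    n, g = X.shape
    ranks = sps.rankdata(X, axis=0)
    tie_terms = np.array([_tie_term(X[:, j]) for j in range(g)])
    expm1 = np.expm1(X)
    frames = []
    for c in clusters:
        mask = labels == c
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 < min_cluster_size:
            warnings.warn(f"cluster {c} has fewer than {min_cluster_size} cells; skipped")
            continue
        r1 = ranks[mask].sum(axis=0)
        mean_r1 = n1 * (n + 1) / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(var > 0, (r1 - mean_r1) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
        p = np.where(var > 0, 2.0 * sps.norm.sf(np.abs(z)), 1.0)
        p_adj = benjamini_hochberg(p)
        mean_in = expm1[mask].mean(axis=0)
        mean_out = expm1[~mask].mean(axis=0)
        lfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": nm.gene_symbols,
                    "z": z,
                    "lfc": lfc,
                    "p": p,
                    "p_adj": p_adj,
                    "significant": (p_adj < alpha) & (lfc > lfc_threshold),
                }
            )
        )
    if not frames:
        raise ValueError("no cluster large enough to test")
    return pd.concat(frames, ignore_index=True)


def embed_umap(e: Embedding, seed: int = 0) -> np.ndarray:
    """2-D UMAP of the PCA embedding, for visual reporting only (no
    downstream statistic depends on these coordinates)."""
    import umap  # deferred: only needed when a map is actually drawn

    return umap.UMAP(n_components=2, random_state=seed).fit_transform(e.coords)
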