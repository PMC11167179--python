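"""Marker-based meta-cluster annotation and functional-module assignment.

Clusters are labeled at the cluster level (majority program): each cluster
gets the meta-cluster whose marker genes have the highest mean z-scored
expression. Meta-clusters then map onto the two functional modules —
immune-promoting Module 1 (Tfh + effector) and immunosuppressive Module 2
(Treg); naive cells sit outside both modules and are excluded from the
exhaustion analysis. Proliferative and heat-shock gene sets are auxiliary
annotation tags only; clusters dominated by them still inherit a
Treg/Tfh/effector/naive program from the main dictionary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .io_10x import NormMatrix
from .synthdata import AUX_GENES, MARKER_GENES

#: tie-break priority when marker-mean z-scores are exactly equal
META_PRIORITY = ("Treg", "Tfh", "effector", "naive")

#: fixed meta-cluster -> module map; naive cells belong to neither module
MODULE_OF = {"effector": 1, "Tfh": 1, "Treg": 2, "naive": None}


def default_marker_dictionary() -> dict[str, list[str]]:
    """Canonical program markers; user-overridable copy."""
    return {m: list(g) for m, g in MARKER_GENES.items()}


def auxiliary_tags() -> dict[str, list[str]]:
    return {k: list(v) for k, v in AUX_GENES.items()}


def assign_meta_clusters(
    nm: NormMatrix,
    labels: np.ndarray,
    marker_dict: dict[str, list[str]] | None = None,
) -> dict[int, str]:
    """Map each cluster to the meta-cluster with the highest mean marker
    z-score; exact ties resolve by the fixed priority Treg > Tfh > effector
    > naive. Dictionary genes absent from the matrix are dropped (error only
    when a program loses all its genes)."""
    marker_dict = marker_dict or default_marker_dictionary()
    labels = np.asarray(labels)
    sym = nm.symbol_index()
    X = np.asarray(nm.X.todense())
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    resolved = {}
    for meta, genes in marker_dict.items():
        cols = [sym[g] for g in genes if g in sym]
        if not cols:
            raise ValueError(f"no marker gene of program {meta!r} present in the matrix")
        resolved[meta] = cols

    priority = {m: i for i, m in enumerate(META_PRIORITY)}
    metas = sorted(resolved, key=lambda m: priority.get(m, len(priority)))
    out: dict[int, str] = {}
    for c in sorted(pd.unique(labels).tolist()):
        mask = labels == c
        best, best_score = None, -np.inf
        for meta in metas:
            score = Z[np.ix_(mask, resolved[meta])].mean()
            if score > best_score:  # strict: earlier (higher-priority) meta wins ties
                best, best_score = meta, score
        out[int(c)] = best
    return out


def assign_modules(meta_labels) -> np.ndarray:
    """Per-cell module labels from meta-cluster labels: effector/Tfh -> 1,
    Treg -> 2, naive -> None."""
    meta_labels = np.asarray(meta_labels, dtype=object)
    unknown = set(meta_labels) - set(MODULE_OF)
    if unknown:
        raise ValueError(f"unknown meta-cluster labels: {sorted(map(str, unknown))}")
    return np.array([MODULE_OF[m] for m in meta_labels], dtype=object)


def top_markers(markers: pd.DataFrame, top_k: int = 20) -> dict[int, list[str]]:
    """Top ``top_k`` significant markers per cluster by adjusted p (ties by
    raw p then gene symbol)."""
    out = {}
    for c, grp in markers[markers["significant"]].groupby("cluster"):
        grp = grp.sort_values(["p_adj", "p", "gene"], kind="stable")
        out[int(c)] = grp["gene"].head(top_k).tolist()
    return out


def reorder_feature_matrix(
    nm: NormMatrix, markers: pd.DataFrame, top_k: int = 20
) -> tuple[list[str], pd.DataFrame]:
    """Correlation structure of the union of top-``top_k`` cluster markers.

    Pearson gene-gene correlations over all cells are reordered by
    average-linkage hierarchical clustering on distance 1 - r so that
    co-expressed feature blocks sit contiguously. Returns the ordered gene
    list and the reordered correlation matrix. Deterministic: the gene union
    is sorted before linkage, so ties resolve by gene symbol.
    """
    union: set[str] = set()
    for genes in top_markers(markers, top_k=top_k).values():
        union.update(genes)
    genes = sorted(union)
    if len(genes) < 2:
        raise ValueError("need at least 2 marker genes to reorder")
    sym = nm.symbol_index()
    cols = [sym[g] for g in genes if g in sym]
    genes = [nm.gene_symbols[c] for c in cols]
    X = np.asarray(nm.X[:, cols].todense())
    sd = X.std(axis=0)
    keep = sd > 0
    genes = [g for g, k in zip(genes, keep) if k]
    X = X[:, keep]
    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - corr
    # condensed distance for average linkage; clip tiny negatives from fp noise
    iu = np.triu_indices(len(genes), k=1)
    condensed = np.maximum(dist[iu], 0.0)
    link = sch.linkage(condensed, method="average")
    order = sch.leaves_list(link)
    ordered = [genes[i] for i in order]
    reordered = pd.DataFrame(corr[np.ix_(order, order)], index=ordered, columns=ordered)
    return ordered, reordered
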