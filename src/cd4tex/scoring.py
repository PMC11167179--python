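"""Exhaustion and functional scoring of CD4+ T cells.

The central statistic is a binned-background module score: the mean
log-normalized expression of a gene panel in a cell minus the mean of
expression-matched control genes, where controls are drawn from
equal-frequency bins of population average expression. Exhaustion panels are
derived per module as the top-30 genes most Pearson-correlated with an
anchor inhibitory receptor (PDCD1 for Module 1, TIGIT for Module 2); cells
scoring above the population mean are called exhausted (Tex). Suppressive
and effective scores use fixed literature panels; the chemotaxis score uses
the top-30 CXCL13-correlated genes in Tfh cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_10x import NormMatrix
from .stats import kruskal_wallis, welch_t
from .synthdata import ANCHORS, EFFECTIVE_PANEL, SUPPRESSIVE_PANEL


@dataclass
class GenePanel:
    """Named ordered gene list; either fixed or derived from an anchor."""

    name: str
    genes: list[str]
    derivation: str = "fixed"  # or "anchor_correlated"
    anchor: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")
        if self.anchor is not None and self.anchor in self.genes:
            raise ValueError("anchor may not appear in its own derived panel")

    def to_dict(self) -> dict:
        return {"name": self.name, "genes": list(self.genes),
                "derivation": self.derivation, "anchor": self.anchor}

    @classmethod
    def from_dict(cls, d: dict) -> "GenePanel":
        return cls(name=d["name"], genes=list(d["genes"]),
                   derivation=d.get("derivation", "fixed"), anchor=d.get("anchor"))


def fixed_panels() -> dict[str, GenePanel]:
    """The literature-derived suppressive and effective function panels."""
    return {
        "suppressive": GenePanel("suppressive", list(SUPPRESSIVE_PANEL)),
        "effective": GenePanel("effective", list(EFFECTIVE_PANEL)),
    }


@dataclass
class ScoreVector:
    """Per-cell scores for one panel over one scored population."""

    panel_name: str
    cell_ids: list[str]
    values: np.ndarray
    n_bins: int
    n_ctrl: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.cell_ids):
            raise ValueError("score length must match cell count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.cell_ids, name=self.panel_name)


@dataclass
class TexCall:
    """Exhaustion calls for one scored population (threshold = mean score)."""

    flags: np.ndarray  # "Tex" / "nonTex" per cell
    threshold: float
    cell_ids: list[str]
    scope: str = ""

    def series(self) -> pd.Series:
        return pd.Series(self.flags, index=self.cell_ids, name="tex_flag")


def _resolve_panel(nm: NormMatrix, panel: GenePanel) -> list[int]:
    sym = nm.symbol_index()
    cols, missing = [], []
    for g in panel.genes:
        (cols if g in sym else missing).append(sym.get(g, g))
    if missing:
        warnings.warn(f"panel {panel.name!r}: {len(missing)} genes absent, scored on the rest")
    if not cols:
        raise ValueError(f"panel {panel.name!r} has no genes present in the matrix")
    return cols


def derive_anchor_panel(
    nm: NormMatrix,
    cells: np.ndarray | None,
    anchor: str,
    k: int = 30,
    name: str | None = None,
) -> GenePanel:
    """Top-``k`` genes by Pearson correlation with ``anchor`` over the
    selected cells (descending, ties by gene id); zero-variance genes and the
    anchor itself are excluded."""
    sub = nm if cells is None else nm.subset_cells(np.asarray(cells))
    sym = sub.symbol_index()
    if anchor not in sym:
        raise ValueError(f"anchor gene {anchor!r} not present")
    X = np.asarray(sub.X.todense())
    a = X[:, sym[anchor]]
    if a.std() == 0:
        raise ValueError(f"anchor gene {anchor!r} has zero variance in the selected cells")
    ac = a - a.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ ac / np.maximum(denom, 1e-300), np.nan)
    eligible = np.isfinite(r)
    eligible[sym[anchor]] = False
    idx = np.flatnonzero(eligible)
    if idx.size < k:
        warnings.warn(f"only {idx.size} eligible genes for anchor {anchor}; returning all")
        k = idx.size
    gene_ids = np.asarray(sub.gene_ids, dtype=object)
    order = idx[np.lexsort((gene_ids[idx], -r[idx]))]
    genes = [sub.gene_symbols[i] for i in order[:k]]
    return GenePanel(name=name or f"{anchor}_top{k}", genes=genes,
                     derivation="anchor_correlated", anchor=anchor)


def expression_bins(nm: NormMatrix, n_bins: int = 24) -> np.ndarray:
    """Equal-frequency bins of population average expression, per gene.

    Genes are ranked by mean expression (ties by gene id for determinism) and
    cut into ``n_bins`` nearly equal chunks; returns a bin index per gene.
    """
    if nm.n_genes < n_bins:
        raise ValueError("need at least n_bins genes")
    avg = np.asarray(nm.X.mean(axis=0)).ravel()
    order = np.lexsort((np.asarray(nm.gene_ids, dtype=object), avg))
    bins = np.empty(nm.n_genes, dtype=int)
    edges = np.linspace(0, nm.n_genes, n_bins + 1).astype(int)
    for b in range(n_bins):
        bins[order[edges[b] : edges[b + 1]]] = b
    return bins


def module_score(
    nm: NormMatrix,
    cells: np.ndarray | None,
    panel: GenePanel,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_genes: list[str] | None = None,
) -> ScoreVector:
    """Binned-background module score over the selected cells.

    For each panel gene, ``n_ctrl`` control genes are sampled (without
    replacement where the bin allows) from the gene's average-expression bin;
    the score is the mean expression over panel genes minus the mean over the
    pooled control draw. ``control_genes`` overrides sampling (test hook).
    Deterministic given ``seed``.
    """
    sub = nm if cells is None else nm.subset_cells(np.asarray(cells))
    cols = _resolve_panel(sub, panel)
    X = sub.X.tocsc()
    if control_genes is not None:
        sym = sub.symbol_index()
        ctrl_cols = np.array([sym[g] for g in control_genes if g in sym])
        if ctrl_cols.size == 0:
            raise ValueError("no control genes present")
    else:
        bins = expression_bins(sub, n_bins=n_bins)
        rng = np.random.default_rng(seed)
        pools = []
        for c in cols:
            bin_members = np.flatnonzero(bins == bins[c])
            if bin_members.size >= n_ctrl:
                pools.append(rng.choice(bin_members, size=n_ctrl, replace=False))
            else:
                pools.append(rng.choice(bin_members, size=n_ctrl, replace=True))
        ctrl_cols = np.concatenate(pools)
    panel_mean = np.asarray(X[:, cols].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_cols].mean(axis=1)).ravel()
    return ScoreVector(
        panel_name=panel.name,
        cell_ids=list(sub.cell_ids),
        values=panel_mean - ctrl_mean,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def classify_tex(scores: ScoreVector, scope: str = "") -> TexCall:
    """Call cells exhausted when their score strictly exceeds the population
    mean score (cells exactly at the mean are nonTex)."""
    if scores.values.size < 2:
        raise ValueError("need at least 2 cells to classify")
    threshold = float(scores.values.mean())
    if np.all(scores.values == scores.values[0]):
        warnings.warn("all scores identical; every cell called nonTex")
    flags = np.where(scores.values > threshold, "Tex", "nonTex")
    return TexCall(flags=flags, threshold=threshold, cell_ids=list(scores.cell_ids), scope=scope)


def functional_scores(
    nm: NormMatrix,
    cells: np.ndarray | None,
    tfh_cells: np.ndarray | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    chemotaxis_k: int = 30,
) -> dict[str, ScoreVector]:
    """Suppressive, effective and chemotaxis scores over the selected cells.

    The suppressive and effective panels are fixed; the chemotaxis panel is
    the top-``chemotaxis_k`` CXCL13-correlated genes derived over
    ``tfh_cells`` (falling back to the scored population when not given).
    All three use the same scoring parameters.
    """
    panels = fixed_panels()
    chemo = derive_anchor_panel(
        nm, tfh_cells if tfh_cells is not None else cells, ANCHORS["chemotaxis"],
        k=chemotaxis_k, name="chemotaxis",
    )
    panels["chemotaxis"] = chemo
    return {
        name: module_score(nm, cells, panel, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        for name, panel in panels.items()
    }


def compare_scores(scores: ScoreVector | np.ndarray, groups, test: str = "kruskal_wallis"):
    """Compare score distributions across groups.

    ``kruskal_wallis`` returns (H, p) for any number of groups;
    ``welch_t`` returns (t, p) and requires exactly two groups.
    """
    values = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("scores and group labels must align")
    labels = pd.unique(groups)
    samples = [values[groups == lab] for lab in labels]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if test == "kruskal_wallis":
        return kruskal_wallis(*samples)
    if test == "welch_t":
        if len(samples) != 2:
            raise ValueError("welch_t requires exactly 2 groups")
        t, _, p = welch_t(samples[0], samples[1])
        return t, p
    raise ValueError(f"unknown test {test!r}")
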