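"""Clonotype calling from scTCR-seq contigs and clonal-expansion statistics.

Clonotypes are defined by the V(D)J gene calls of the TRA and TRB chains
(CDR3-inclusive strict mode optional). Expansion bins follow the cell-count
rule: single (0 < X <= 1), double (1 < X <= 2), multiple (X > 2), where X is
the number of cells carrying the clonotype. Composition across groups is
compared with a Pearson chi-square test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import pearson_chi2

logger = logging.getLogger(__name__)

EXPANSION_BINS = ("single", "double", "multiple")


def expansion_bin(x: int) -> str:
    """Bin a clonotype by its cell count X: single (X<=1), double (X==2),
    multiple (X>2)."""
    if x < 1:
        raise ValueError("clonotype size must be >= 1")
    if x <= 1:
        return "single"
    if x <= 2:
        return "double"
    return "multiple"


def _best_per_chain(contigs: pd.DataFrame) -> pd.DataFrame:
    """Resolve multi-contig barcodes: keep the highest-UMI contig per
    (barcode, chain); deterministic ties by contig order."""
    df = contigs.copy()
    if "umis" in df.columns:
        df = df.sort_values("umis", ascending=False, kind="stable")
    return df.drop_duplicates(subset=["barcode", "chain"], keep="first")


def call_clonotypes(
    contigs: pd.DataFrame,
    cell_ids,
    include_cdr3: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group cells into clonotypes by their concatenated TRA/TRB gene calls.

    ``cell_ids`` is the barcode universe of the expression data; contig
    barcodes outside it are dropped (count logged). Missing chains contribute
    ``NA`` key components. Returns ``(cells, clonotypes)``: a per-cell frame
    (cell_id, clonotype_id, clone_size, expansion_bin) and a per-clonotype
    frame (clonotype_id, key, size, expansion_bin).
    """
    cell_set = set(map(str, cell_ids))
    if contigs.empty:
        raise ValueError("empty contig table")
    df = contigs[contigs["barcode"].astype(str).isin(cell_set)]
    n_dropped = len(contigs) - len(df)
    if n_dropped:
        logger.info("call_clonotypes: dropped %d contigs without expression barcodes", n_dropped)
    if df.empty:
        raise ValueError("no contig barcode overlaps the expression cell table")
    best = _best_per_chain(df)

    def chain_key(row, chain):
        if row is None:
            return "NA"
        fields = [row["v_gene"], row["j_gene"]] if chain == "TRA" else [row["v_gene"], row["d_gene"], row["j_gene"]]
        if include_cdr3:
            fields.append(row["cdr3"])
        return ".".join(str(f) for f in fields)

    keys = {}
    for bc, grp in best.groupby("barcode", sort=True):
        tra = grp[grp["chain"] == "TRA"]
        trb = grp[grp["chain"] == "TRB"]
        ka = chain_key(tra.iloc[0], "TRA") if len(tra) else "NA"
        kb = chain_key(trb.iloc[0], "TRB") if len(trb) else "NA"
        keys[str(bc)] = f"TRA:{ka}_TRB:{kb}"

    cells = pd.DataFrame({"cell_id": list(keys), "key": list(keys.values())})
    sizes = cells["key"].value_counts()
    # deterministic ids: descending size, ties by key string
    ordered = sorted(sizes.index, key=lambda k: (-sizes[k], k))
    id_of = {k: f"clonotype{i + 1:05d}" for i, k in enumerate(ordered)}
    cells["clonotype_id"] = cells["key"].map(id_of)
    cells["clone_size"] = cells["key"].map(sizes).astype(int)
    cells["expansion_bin"] = cells["clone_size"].map(expansion_bin)
    clonotypes = pd.DataFrame(
        {
            "clonotype_id": [id_of[k] for k in ordered],
            "key": ordered,
            "size": [int(sizes[k]) for k in ordered],
        }
    )
    clonotypes["expansion_bin"] = clonotypes["size"].map(expansion_bin)
    return cells.drop(columns="key").sort_values("cell_id").reset_index(drop=True), clonotypes


def expansion_composition(
    cell_bins: pd.DataFrame,
    groups: pd.Series | dict,
    samples: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Cell counts per group x expansion bin, plus optional per-sample
    percentages.

    ``cell_bins`` is the per-cell frame from :func:`call_clonotypes`;
    ``groups`` maps cell_id to a group label (cells without a group are
    excluded with a warning-level log line). Percentages are per (sample,
    group): 100 * cells in bin / cells in that group and sample.
    """
    df = cell_bins.copy()
    gmap = groups if isinstance(groups, dict) else groups.to_dict()
    df["group"] = df["cell_id"].map(gmap)
    n_missing = int(df["group"].isna().sum())
    if n_missing:
        logger.warning("expansion_composition: %d cells lack a group label; excluded", n_missing)
        df = df.dropna(subset=["group"])
    if df.empty:
        raise ValueError("no grouped cells to tabulate")
    table = (
        df.groupby(["group", "expansion_bin"], observed=False).size().unstack(fill_value=0)
        .reindex(columns=list(EXPANSION_BINS), fill_value=0)
    )
    pct = None
    if samples is not None:
        smap = samples if isinstance(samples, dict) else samples.to_dict()
        df["sample"] = df["cell_id"].map(smap)
        counts = df.groupby(["sample", "group", "expansion_bin"], observed=False).size()
        totals = df.groupby(["sample", "group"], observed=False).size()
        pct = (100.0 * counts / totals).rename("percent").reset_index()
    return table, pct


def chisq_compare(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a group x bin table."""
    values = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
    return pearson_chi2(values)
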