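"""Readers/writers for the 10x CellRanger matrix dialect and VDJ contig tables.

The on-disk formats are the uncompressed CellRanger v3 triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``; gzipped variants are
accepted on read) and the ``filtered_contig_annotations.csv`` VDJ table.
Internally cells are rows and genes are columns, both 0-indexed; the
MatrixMarket file stores the transposed (feature x barcode) matrix with
1-based indices, as CellRanger does.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VDJ_REQUIRED_COLUMNS = ("barcode", "chain", "v_gene", "d_gene", "j_gene", "cdr3")
VALID_CHAINS = ("TRA", "TRB")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


def _dedup_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate repeated gene symbols by suffixing ``.1``, ``.2``, ...

    Gene ids stay the primary key; only the symbol namespace is patched,
    mirroring common 10x loader behaviour.
    """
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


@dataclass
class CountMatrix:
    """Sparse integer UMI counts, cells x genes."""

    X: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    gene_symbols: list[str]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        n_cells, n_genes = self.X.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise ValueError("gene id/symbol length does not match matrix columns")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids are not unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.X.dtype, np.integer):
            data = self.X.data
            if self.X.nnz and not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
            self.X = self.X.astype(np.int64)
        self.gene_symbols = _dedup_symbols([str(s) for s in self.gene_symbols])

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def symbol_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.gene_symbols)}


@dataclass
class NormMatrix:
    """Log-normalized expression, cells x genes (same axes as CountMatrix)."""

    X: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    gene_symbols: list[str]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X, dtype=np.float64)
        if len(self.cell_ids) != self.X.shape[0]:
            raise ValueError("cell id length mismatch")
        if len(self.gene_ids) != self.X.shape[1] or len(self.gene_symbols) != self.X.shape[1]:
            raise ValueError("gene id/symbol length mismatch")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def symbol_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.gene_symbols)}

    def subset_cells(self, mask: np.ndarray) -> "NormMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormMatrix(
            self.X[idx],
            [self.cell_ids[i] for i in idx],
            self.gene_ids,
            self.gene_symbols,
        )


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {dir_path}")


def read_10x(dir_path: str | Path) -> CountMatrix:
    """Read a CellRanger matrix directory into a cells x genes CountMatrix.

    Accepts gzipped or plain files. Raises :class:`FormatError` when a file
    is missing or the MTX header disagrees with the TSV lengths.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_file(dir_path, "matrix.mtx")
    feat_path = _find_file(dir_path, "features.tsv")
    bc_path = _find_file(dir_path, "barcodes.tsv")

    with _open_maybe_gz(feat_path) as fh:
        features = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if features.shape[1] < 2:
        raise FormatError("features.tsv must have at least id and symbol columns")
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    with _open_maybe_gz(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except ValueError as exc:
            raise FormatError(f"malformed MatrixMarket file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix.mtx declares {mat.shape} but features.tsv has "
            f"{len(features)} rows and barcodes.tsv has {len(barcodes)}"
        )
    X = sp.csr_matrix(mat.T)
    return CountMatrix(
        X=X,
        cell_ids=barcodes,
        gene_ids=features[0].tolist(),
        gene_symbols=features[1].tolist(),
    )


def write_10x(m: CountMatrix, dir_path: str | Path) -> None:
    """Write the CellRanger v3 uncompressed triplet (features x barcodes MTX)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(m.X.T)
    # write MTX by hand: coordinate integer general, deterministic entry order
    order = np.lexsort((coo.row, coo.col))
    with open(dir_path / "matrix.mtx", "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write("%\n")
        fh.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for k in order:
            fh.write(f"{coo.row[k] + 1} {coo.col[k] + 1} {coo.data[k]}\n")
    with open(dir_path / "features.tsv", "w") as fh:
        for gid, sym in zip(m.gene_ids, m.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for bc in m.cell_ids:
            fh.write(bc + "\n")


def read_contigs(path: str | Path) -> pd.DataFrame:
    """Read a 10x ``filtered_contig_annotations.csv`` table.

    Rows whose chain is neither TRA nor TRB are dropped (count logged).
    Raises :class:`FormatError` on missing required columns.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"contig file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in VDJ_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig table missing required columns: {missing}")
    if "umis" in df.columns:
        df["umis"] = pd.to_numeric(df["umis"], errors="coerce").fillna(0).astype(int)
    keep = df["chain"].isin(VALID_CHAINS)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_contigs: dropped %d rows with non-TRA/TRB chains", n_dropped)
    out = df.loc[keep].reset_index(drop=True)
    if out["barcode"].astype(str).str.len().eq(0).any():
        raise FormatError("contig table contains empty barcodes")
    return out


def write_contigs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
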