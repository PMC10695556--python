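"""Readers and writers for the on-disk formats.

A "count bundle" is a 10x-style directory: ``matrix.mtx`` (MatrixMarket
coordinate integer, genes x cells, 1-based indices), ``features.tsv`` (one
gene id per line), ``barcodes.tsv`` (one barcode per line) and
``cell_metadata.tsv`` (barcode, donor_id, cell_type, is_doublet, ...).
Donor designs, ground-truth tables, DEG tables, QC reports and permutation
summaries are plain TSV. MatrixMarket indices are 1-based on disk and
0-based in memory; the conversion lives entirely in this module (scipy
handles it).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CellCountMatrix, DonorDesign
from .simulate import GroundTruth

__all__ = [
    "read_count_bundle",
    "write_count_bundle",
    "read_donor_design",
    "write_donor_design",
    "write_ground_truth",
    "read_ground_truth",
    "read_deg_table",
    "write_deg_table",
]

#: published DEG-table dialect used on disk
_DEG_OUT_COLS = ["Cell", "logFC", "logCPM", "LR", "p-Value", "adj_pval", "HGNC"]
_DEG_RENAME = {
    "cell_type": "Cell",
    "gene": "HGNC",
    "p_value": "p-Value",
}


def write_count_bundle(matrix: CellCountMatrix, directory) -> Path:
    """Write matrix.mtx + features/barcodes/cell_metadata TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if matrix.counts.size and matrix.counts.min() < 0:
        raise ValueError("negative counts cannot be written")
    coo = matrix.counts.tocoo()
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"),
        sp.coo_matrix(
            (coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape
        ),
        field="integer",
    )
    pd.Series(matrix.gene_ids).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(matrix.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )
    matrix.cell_metadata.to_csv(
        directory / "cell_metadata.tsv", sep="\t", index=False
    )
    return directory


def read_count_bundle(directory) -> CellCountMatrix:
    """Read a count bundle back; errors on dimension mismatches and
    duplicate barcodes."""
    directory = Path(directory)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv", "cell_metadata.tsv"):
        if not (directory / fname).exists():
            raise FileNotFoundError(f"{directory} is missing {fname}")
    counts = sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")))
    genes = pd.read_csv(
        directory / "features.tsv", sep="\t", header=None
    )[0].to_numpy(dtype=object)
    barcodes = pd.read_csv(
        directory / "barcodes.tsv", sep="\t", header=None
    )[0].to_numpy(dtype=object)
    if counts.shape[0] != len(genes):
        raise ValueError(
            f"matrix has {counts.shape[0]} rows but features.tsv has {len(genes)}"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[1]} columns but barcodes.tsv has "
            f"{len(barcodes)}"
        )
    meta = pd.read_csv(directory / "cell_metadata.tsv", sep="\t")
    if meta["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in cell_metadata.tsv")
    if len(meta) != len(barcodes):
        raise ValueError("cell_metadata.tsv length does not match barcodes.tsv")
    # align metadata rows to the barcode order of barcodes.tsv
    meta = (
        meta.set_index("barcode").loc[barcodes].reset_index()
    )
    if "is_doublet" in meta:
        meta["is_doublet"] = meta["is_doublet"].astype(bool)
    return CellCountMatrix(counts=counts, gene_ids=genes, cell_metadata=meta)


def write_donor_design(design: DonorDesign, path) -> Path:
    path = Path(path)
    design.table.to_csv(path, sep="\t", index=False)
    return path


def read_donor_design(path) -> DonorDesign:
    return DonorDesign(pd.read_csv(path, sep="\t"))


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    truth.table.to_csv(path, sep="\t", index=False)
    return path


def read_ground_truth(path) -> GroundTruth:
    t = pd.read_csv(path, sep="\t")
    t["is_de"] = t["is_de"].astype(bool)
    return GroundTruth(t)


def write_deg_table(table: pd.DataFrame, path) -> Path:
    """Write a DEG table in the published column dialect.

    Columns absent from the input (e.g. ``LR`` for the cell-level test)
    are emitted empty.
    """
    path = Path(path)
    out = table.rename(columns=_DEG_RENAME).copy()
    for col in _DEG_OUT_COLS:
        if col not in out:
            out[col] = np.nan
    out[_DEG_OUT_COLS].to_csv(path, sep="\t", index=False)
    return path


def read_deg_table(path) -> pd.DataFrame:
    """Read a DEG table, converting to the internal column dialect."""
    t = pd.read_csv(path, sep="\t")
    return t.rename(columns={v: k for k, v in _DEG_RENAME.items()})
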