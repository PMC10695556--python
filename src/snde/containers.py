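"""In-memory containers shared across the pipeline.

The package works on gene x cell sparse integer count matrices with
cell-level annotations (donor, cell type, doublet flag) and a donor-level
design table carrying the case/control condition. Donors — not cells — are
the unit of biological replication; every container keeps the donor
identifiers attached so downstream modules can aggregate or permute at the
donor level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONDITION_CASE = "case"
CONDITION_CONTROL = "control"

#: required columns of the per-cell metadata table
CELL_METADATA_COLUMNS = ("barcode", "donor_id", "cell_type", "is_doublet")


@dataclass
class CellCountMatrix:
    """Sparse gene x cell integer counts plus aligned annotations.

    Attributes
    ----------
    counts:
        ``scipy.sparse`` matrix of shape ``(n_genes, n_cells)`` holding raw
        integer counts.
    gene_ids:
        Gene symbols, length ``n_genes``. Mitochondrial genes follow the
        human convention of an ``MT-`` prefix unless a list is supplied
        explicitly to the QC routines.
    cell_metadata:
        One row per cell, indexed 0..n_cells-1, with at least the columns
        ``barcode``, ``donor_id``, ``cell_type`` and ``is_doublet``.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"matrix has {self.counts.shape[0]} genes but "
                f"{len(self.gene_ids)} gene ids"
            )
        if self.counts.shape[1] != len(self.cell_metadata):
            raise ValueError(
                f"matrix has {self.counts.shape[1]} cells but metadata has "
                f"{len(self.cell_metadata)} rows"
            )
        missing = [c for c in CELL_METADATA_COLUMNS if c not in self.cell_metadata]
        if missing:
            raise ValueError(f"cell metadata missing columns: {missing}")
        barcodes = self.cell_metadata["barcode"]
        if barcodes.duplicated().any():
            dupes = barcodes[barcodes.duplicated()].unique()[:5]
            raise ValueError(f"duplicate barcodes: {list(dupes)}")
        self.cell_metadata = self.cell_metadata.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> np.ndarray:
        return self.cell_metadata["barcode"].to_numpy()

    def subset_cells(self, mask: np.ndarray) -> "CellCountMatrix":
        """Return a copy restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise TypeError("cell mask must be boolean")
        return CellCountMatrix(
            counts=self.counts[:, mask],
            gene_ids=self.gene_ids,
            cell_metadata=self.cell_metadata.loc[mask].reset_index(drop=True),
        )

    def subset_genes(self, mask: np.ndarray) -> "CellCountMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise TypeError("gene mask must be boolean")
        return CellCountMatrix(
            counts=self.counts[mask, :],
            gene_ids=self.gene_ids[mask],
            cell_metadata=self.cell_metadata,
        )


@dataclass
class DonorDesign:
    """Donor-level condition labels — the unit of biological replication.

    ``table`` has one row per donor with columns ``donor_id`` and
    ``condition`` (values ``case`` / ``control``); extra covariate columns
    are carried along untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("donor_id", "condition"):
            if col not in self.table:
                raise ValueError(f"donor design missing column {col!r}")
        if self.table["donor_id"].duplicated().any():
            raise ValueError("duplicate donor ids in design")
        bad = set(self.table["condition"]) - {CONDITION_CASE, CONDITION_CONTROL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def donor_ids(self) -> np.ndarray:
        return self.table["donor_id"].to_numpy()

    @property
    def condition(self) -> pd.Series:
        return self.table.set_index("donor_id")["condition"]

    def is_case(self) -> pd.Series:
        """Boolean per donor (indexed by donor_id): True for cases."""
        return self.condition == CONDITION_CASE

    def group_sizes(self) -> dict:
        return self.table["condition"].value_counts().to_dict()


@dataclass
class PseudobulkMatrix:
    """Gene x sample summed counts, one sample per donor within a cell type.

    ``counts`` is dense (samples are few), shape ``(n_genes, n_samples)``;
    ``samples`` has columns ``donor_id``, ``cell_type``, ``n_cells``.
    ``lib_size`` is the per-sample column sum and ``norm_factors`` the
    TMM-style normalization factors (1.0 until computed).
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    samples: pd.DataFrame
    norm_factors: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("pseudobulk counts shape does not match labels")
        if self.norm_factors is None:
            self.norm_factors = np.ones(self.counts.shape[1])
        self.samples = self.samples.reset_index(drop=True)

    @property
    def lib_size(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]
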