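"""Nucleus-level quality-control cascade.

The cascade applies, per cell: fixed minimums on library size and on the
number of expressed genes (200 each), adaptive *upper* thresholds at
median + 4 MAD on both quantities, a mitochondrial-fraction cut-off
(default: fail at >= 0.10), and removal of flagged doublets. "Expressed
genes" are counted against a dataset-level mask: a gene counts as expressed
only if it has at least 2 counts in at least 3 cells of the full pre-QC
matrix.

A cell can fail several criteria at once, so per-criterion failure counts
overlap; only total-failed plus total-passed is guaranteed to sum to the
input cell count. The summary table reports both, mirroring the standard
multi-criterion QC accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellCountMatrix

__all__ = [
    "CellQCMetrics",
    "QCThresholds",
    "QCResult",
    "compute_cell_qc",
    "expressed_gene_mask",
    "mad_upper_threshold",
    "apply_qc",
    "run_qc",
]

#: order of criteria in reports
CRITERIA = (
    "min_library_size",
    "max_library_size",
    "min_expressed_genes",
    "max_expressed_genes",
    "mito_fraction",
    "doublet",
)


@dataclass
class CellQCMetrics:
    """Per-cell QC quantities.

    ``mito_fraction`` is defined as 0 for all-zero cells; such cells are
    marked in ``zero_total`` (they will fail the library-size minimum
    anyway, but the degenerate division is made explicit).
    """

    total_counts: np.ndarray
    n_expressed_genes: np.ndarray
    mito_fraction: np.ndarray
    doublet_flag: np.ndarray
    zero_total: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.total_counts)


@dataclass
class QCThresholds:
    """Cut-offs of the cascade.

    ``mito_strict`` selects whether the mitochondrial criterion fires at
    ``>= mito_max`` (the default, matching the operational accounting) or
    strictly ``> mito_max``. ``mad_consistency`` optionally multiplies the
    MAD by the 1.4826 normal-consistency constant; off by default, so
    "4 MAD" means four raw median absolute deviations.
    """

    min_library_size: int = 200
    min_expressed_genes: int = 200
    mad_multiplier: float = 4.0
    mito_max: float = 0.10
    expressed_gene_min_counts: int = 2
    expressed_gene_min_cells: int = 3
    drop_doublets: bool = True
    mito_strict: bool = False  # False: fail at >= mito_max
    mad_consistency: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.mito_max <= 1:
            raise ValueError("mito_max must be in (0, 1]")
        for name in (
            "min_library_size",
            "min_expressed_genes",
            "mad_multiplier",
            "expressed_gene_min_counts",
            "expressed_gene_min_cells",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCResult:
    """Per-cell criterion flags plus the aggregate accounting table."""

    flags: pd.DataFrame  # boolean column per criterion, one row per cell
    passed: np.ndarray  # per-cell: True if no criterion fired
    summary: pd.DataFrame  # criterion, cells, percentage
    thresholds: QCThresholds = field(repr=False, default=None)

    @property
    def n_passed(self) -> int:
        return int(self.passed.sum())

    @property
    def n_failed(self) -> int:
        return int((~self.passed).sum())


def compute_cell_qc(
    matrix: CellCountMatrix, mito_gene_ids=None
) -> CellQCMetrics:
    """Per-cell totals, expressed-gene counts and mitochondrial fractions.

    Parameters
    ----------
    matrix:
        Pre-QC counts.
    mito_gene_ids:
        Gene identifiers to treat as mitochondrial. Defaults to genes whose
        id starts with ``MT-`` (human convention). Unknown ids are an error.
    """
    gene_ids = matrix.gene_ids.astype(str)
    if mito_gene_ids is None:
        mito_mask = np.char.startswith(gene_ids, "MT-")
    else:
        mito_gene_ids = list(mito_gene_ids)
        unknown = sorted(set(mito_gene_ids) - set(gene_ids))
        if unknown:
            raise ValueError(f"unknown mitochondrial gene ids: {unknown}")
        mito_mask = np.isin(gene_ids, mito_gene_ids)

    counts = matrix.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_expr = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_total = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
    zero_total = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero_total, 0.0, mito_total / np.maximum(total, 1))
    doublet = matrix.cell_metadata["is_doublet"].to_numpy(dtype=bool)
    return CellQCMetrics(
        total_counts=total.astype(np.int64),
        n_expressed_genes=n_expr.astype(np.int64),
        mito_fraction=mito_frac,
        doublet_flag=doublet,
        zero_total=zero_total,
    )


def expressed_gene_mask(
    matrix: CellCountMatrix, min_counts: int = 2, min_cells: int = 3
) -> np.ndarray:
    """Genes with >= ``min_counts`` counts in >= ``min_cells`` cells."""
    if min_counts < 1 or min_cells < 1:
        raise ValueError("thresholds must be >= 1")
    qualifying = np.asarray(
        (matrix.counts >= min_counts).sum(axis=1)
    ).ravel()
    return qualifying >= min_cells


def mad_upper_threshold(
    values, n_mads: float = 4.0, consistency: bool = False
) -> float:
    """median + n_mads * MAD; +inf (with a warning) when the MAD is zero.

    With ``consistency=True`` the MAD is multiplied by 1.4826 so that it
    estimates the standard deviation under normality.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite values")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if consistency:
        mad *= 1.4826
    if mad == 0:
        warnings.warn(
            "MAD is zero; upper threshold set to +inf (no outliers flagged)",
            UserWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(med + n_mads * mad)


def apply_qc(metrics: CellQCMetrics, thresholds: QCThresholds) -> QCResult:
    """Evaluate every criterion per cell and build the accounting table."""
    n = metrics.n_cells
    if n == 0:
        flags = pd.DataFrame({c: np.zeros(0, dtype=bool) for c in CRITERIA})
        summary = _summarize(flags, np.zeros(0, dtype=bool), 0)
        return QCResult(flags, np.zeros(0, dtype=bool), summary, thresholds)

    if n >= 2:
        lib_upper = mad_upper_threshold(
            metrics.total_counts,
            thresholds.mad_multiplier,
            thresholds.mad_consistency,
        )
        genes_upper = mad_upper_threshold(
            metrics.n_expressed_genes,
            thresholds.mad_multiplier,
            thresholds.mad_consistency,
        )
    else:
        lib_upper = genes_upper = float("inf")

    if thresholds.mito_strict:
        mito_fail = metrics.mito_fraction > thresholds.mito_max
    else:
        mito_fail = metrics.mito_fraction >= thresholds.mito_max

    flags = pd.DataFrame(
        {
            "min_library_size": metrics.total_counts < thresholds.min_library_size,
            "max_library_size": metrics.total_counts > lib_upper,
            "min_expressed_genes": metrics.n_expressed_genes
            < thresholds.min_expressed_genes,
            "max_expressed_genes": metrics.n_expressed_genes > genes_upper,
            "mito_fraction": mito_fail,
            "doublet": metrics.doublet_flag
            if thresholds.drop_doublets
            else np.zeros(n, dtype=bool),
        }
    )
    passed = ~flags.any(axis=1).to_numpy()
    summary = _summarize(flags, passed, n)
    return QCResult(flags, passed, summary, thresholds)


def _summarize(flags: pd.DataFrame, passed: np.ndarray, n: int) -> pd.DataFrame:
    rows = [("pre_qc", n, 100.0 if n else 0.0)]
    rows.append(("total_failed", int((~passed).sum()), _pct((~passed).sum(), n)))
    for c in CRITERIA:
        rows.append((c, int(flags[c].sum()), _pct(flags[c].sum(), n)))
    rows.append(("total_passed", int(passed.sum()), _pct(passed.sum(), n)))
    return pd.DataFrame(rows, columns=["criterion", "cells", "percentage"])


def _pct(x, n) -> float:
    return round(100.0 * float(x) / n, 2) if n else 0.0


def run_qc(
    matrix: CellCountMatrix,
    thresholds: QCThresholds | None = None,
    mito_gene_ids=None,
) -> tuple[CellCountMatrix, QCResult, np.ndarray]:
    """Full single-pass cascade: gene mask, metrics, filtering.

    The expressed-gene mask is computed once on the full pre-QC matrix;
    per-cell expressed-gene counts then consider masked-in genes only. The
    returned matrix keeps passing cells and masked-in genes.
    """
    thresholds = thresholds or QCThresholds()
    gene_mask = expressed_gene_mask(
        matrix,
        thresholds.expressed_gene_min_counts,
        thresholds.expressed_gene_min_cells,
    )
    masked = matrix.subset_genes(gene_mask)
    # mito fractions use all genes (library composition), expressed-gene
    # counts use the masked matrix
    metrics_all = compute_cell_qc(matrix, mito_gene_ids)
    metrics_masked = compute_cell_qc(masked, None)
    metrics = CellQCMetrics(
        total_counts=metrics_all.total_counts,
        n_expressed_genes=metrics_masked.n_expressed_genes,
        mito_fraction=metrics_all.mito_fraction,
        doublet_flag=metrics_all.doublet_flag,
        zero_total=metrics_all.zero_total,
    )
    result = apply_qc(metrics, thresholds)
    filtered = masked.subset_cells(result.passed)
    return filtered, result, gene_mask
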