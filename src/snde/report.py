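"""Summary statistics and cross-method diagnostics for DEG tables.

Includes the packaged reference DEG tables from the published reanalysis
(one from the originally processed data, one from the reprocessed data),
summary statistics over any DEG table (unique genes, median effect size,
median FDR, per-cell-type composition), the DEG-count vs cell-count
correlation diagnostic, and fold-change concordance between two analyses.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEGSummary",
    "deg_summary",
    "deg_cellcount_correlation",
    "compare_fold_changes",
    "load_paper_fixture",
]

#: sha256 of the packaged fixture files, frozen at transcription time
_FIXTURE_CHECKSUMS = {
    "table2": "568b42d3f57b5e65001a3a028c91765d96fe44f6187b878fd29368678371af33",
    "table4": "d1339293249f5d86cc090ef91cb2fb21e3cbcae3ba81d62bbcf0ac107c48763e",
}
_FIXTURE_FILES = {
    "table2": "table2_degs.tsv",
    "table4": "table4_degs.tsv",
}

#: published-table column dialect -> internal names
_DIALECT = {"Cell": "cell_type", "HGNC": "gene", "p-Value": "p_value"}


def _canonical(table: pd.DataFrame) -> pd.DataFrame:
    """Accept either the internal or the published-table column dialect."""
    t = table.rename(columns=_DIALECT)
    for col in ("gene", "cell_type", "logFC", "adj_pval"):
        if col not in t.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    return t


@dataclass
class DEGSummary:
    """Aggregate description of the significant rows of a DEG table."""

    n_rows: int
    n_unique_genes: int
    median_abs_logfc: float
    median_adj_pval: float
    per_cell_type_counts: dict = field(default_factory=dict)
    per_cell_type_percentages: dict = field(default_factory=dict)
    fdr: float = 0.05

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_unique_genes": self.n_unique_genes,
            "median_abs_logfc": self.median_abs_logfc,
            "median_adj_pval": self.median_adj_pval,
            "per_cell_type_counts": self.per_cell_type_counts,
            "per_cell_type_percentages": self.per_cell_type_percentages,
            "fdr": self.fdr,
        }


def deg_summary(table: pd.DataFrame, fdr: float = 0.05) -> DEGSummary:
    """Summarize the rows of a DEG table significant at ``fdr``.

    Unique genes are distinct gene symbols across cell types; per-cell-type
    percentages are row shares rounded to the nearest integer; medians use
    the midpoint convention for even lengths.
    """
    t = _canonical(table)
    sig = t[t["adj_pval"] < fdr]
    if len(sig) == 0:
        return DEGSummary(0, 0, 0.0, 0.0, {}, {}, fdr)
    counts = sig.groupby("cell_type").size().to_dict()
    percentages = {
        ct: int(round(100.0 * n / len(sig))) for ct, n in counts.items()
    }
    return DEGSummary(
        n_rows=int(len(sig)),
        n_unique_genes=int(sig["gene"].nunique()),
        median_abs_logfc=float(sig["logFC"].abs().median()),
        median_adj_pval=float(sig["adj_pval"].median()),
        per_cell_type_counts=counts,
        per_cell_type_percentages=percentages,
        fdr=fdr,
    )


def deg_cellcount_correlation(deg_counts, cell_counts) -> float:
    """Pearson correlation between per-cell-type DEG counts and cell counts.

    Both arguments are mappings (dict or Series) keyed by cell type; the
    keys must match. Returns NaN with a warning when either vector is
    constant (the correlation is then undefined).
    """
    d = pd.Series(deg_counts)
    c = pd.Series(cell_counts)
    if set(d.index) != set(c.index):
        raise ValueError(
            f"mismatched cell-type keys: {sorted(set(d.index) ^ set(c.index))}"
        )
    if len(d) < 3:
        raise ValueError("need at least 3 cell types")
    c = c.reindex(d.index)
    if d.nunique() == 1 or c.nunique() == 1:
        warnings.warn(
            "constant vector: DEG/cell-count correlation undefined",
            UserWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(stats.pearsonr(d.to_numpy(float), c.to_numpy(float))[0])


def compare_fold_changes(
    table_a: pd.DataFrame, table_b: pd.DataFrame, fdr_cut: float = 0.05
) -> tuple[int, float]:
    """Fold-change concordance between two analyses.

    Joins on (gene, cell type), restricted to rows significant in
    ``table_b`` at ``fdr_cut``, and returns ``(n_genes, Pearson r)`` of the
    paired log2 fold changes; r is NaN when fewer than 3 rows join.
    """
    a = _canonical(table_a)
    b = _canonical(table_b)
    b_sig = b[b["adj_pval"] < fdr_cut]
    joined = a.merge(
        b_sig, on=["gene", "cell_type"], suffixes=("_a", "_b"), how="inner"
    )
    n = len(joined)
    if n < 3:
        return n, float("nan")
    x = joined["logFC_a"].to_numpy(float)
    y = joined["logFC_b"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return n, float("nan")
    return n, float(stats.pearsonr(x, y)[0])


def load_paper_fixture(name: str) -> pd.DataFrame:
    """Load a packaged published DEG table (``table2`` or ``table4``).

    The files are verbatim transcriptions of the printed tables; a sha256
    checksum guards against accidental edits. Returned with the published
    column dialect (``Cell``, ``logFC``, ..., ``HGNC``) untouched.
    """
    if name not in _FIXTURE_FILES:
        raise ValueError(f"unknown fixture {name!r}; choose from table2, table4")
    path = resources.files("snde.data").joinpath(_FIXTURE_FILES[name])
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} checksum mismatch: file was modified "
            f"({digest[:12]}... != {_FIXTURE_CHECKSUMS[name][:12]}...)"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")
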