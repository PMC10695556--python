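"""Cell-level ("pseudoreplication") differential expression.

This is the procedure under study, implemented faithfully so its failure
mode can be measured: every cell is treated as an independent replicate and
case vs control cells are compared per gene with a two-sample Wilcoxon
rank-sum test, followed by BH correction. Because cells from one donor are
correlated, the effective sample size is far smaller than the cell count
and the resulting p-values are anti-conservative — increasingly so as the
number of cells per donor grows.

Expression is normalized per cell to counts-per-ten-thousand and log1p
transformed before testing (configurable back to raw counts); the fold
change is the log2 ratio of group means of the normalized expression with
a small pseudo-count.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellCountMatrix, DonorDesign
from .pseudobulk import bh_adjust

__all__ = ["wilcoxon_de", "cellwise_de", "two_stage_filter"]

_EPS = 1e-9
_EXACT_MAX = 8  # exact enumeration when both groups are at most this size


def _normalize(counts, target_sum=1e4, log1p=True):
    """Counts-per-ten-thousand + log1p, dense (G, C) float array."""
    x = np.asarray(counts.todense(), dtype=float) if hasattr(counts, "todense") else (
        np.asarray(counts, dtype=float)
    )
    tot = x.sum(axis=0)
    scale = np.where(tot > 0, target_sum / np.maximum(tot, 1), 0.0)
    x = x * scale[None, :]
    return np.log1p(x) if log1p else x


def _exact_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumeration (mid-ranks, so ties are
    handled exactly); cost C(n1+n2, n1)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n1)]
    )
    lo = np.mean(sums <= w_obs + 1e-12)
    hi = np.mean(sums >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_de(
    matrix: CellCountMatrix,
    design: DonorDesign,
    cell_type: str,
    normalize: bool = True,
    condition_by_cell: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene rank-sum test between case and control cells of one type.

    ``condition_by_cell`` optionally overrides the condition each cell
    inherits from its donor (used by the permutation benchmark). Returns a
    table with ``gene``, ``cell_type``, ``logFC``, ``p_value``, ``adj_pval``,
    ``n_cells_case``, ``n_cells_control``.
    """
    meta = matrix.cell_metadata
    in_type = (meta["cell_type"] == cell_type).to_numpy()
    if condition_by_cell is None:
        condition_by_cell = meta["donor_id"].map(design.condition)
    cond = np.asarray(condition_by_cell)[in_type]
    sub = matrix.counts[:, in_type]
    case = cond == "case"
    ctrl = cond == "control"
    n1, n2 = int(case.sum()), int(ctrl.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"cell type {cell_type!r}: empty group (case={n1}, control={n2})"
        )

    expr = _normalize(sub) if normalize else np.asarray(sub.todense(), dtype=float)
    xc, xk = expr[:, case], expr[:, ctrl]

    constant = expr.max(axis=1) == expr.min(axis=1)
    if n1 <= _EXACT_MAX and n2 <= _EXACT_MAX:
        p = np.array(
            [_exact_ranksum_p(xc[g], xk[g]) for g in range(expr.shape[0])]
        )
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                xc,
                xk,
                axis=-1,
                alternative="two-sided",
                method="asymptotic",
                use_continuity=True,
            )
        p = np.asarray(res.pvalue)
    p = np.where(constant, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    mean_case = xc.mean(axis=1)
    mean_ctrl = xk.mean(axis=1)
    logfc = np.where(
        constant, 0.0, np.log2((mean_case + _EPS) / (mean_ctrl + _EPS))
    )

    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "cell_type": cell_type,
            "logFC": logfc,
            "p_value": p,
            "adj_pval": bh_adjust(p),
            "n_cells_case": n1,
            "n_cells_control": n2,
        }
    )


def cellwise_de(
    matrix: CellCountMatrix,
    design: DonorDesign,
    normalize: bool = True,
    condition_by_cell: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank-sum DE across every cell type present; BH within cell type."""
    tables = []
    for ct in sorted(matrix.cell_metadata["cell_type"].unique()):
        try:
            tables.append(
                wilcoxon_de(matrix, design, ct, normalize, condition_by_cell)
            )
        except ValueError:
            continue
    if not tables:
        return pd.DataFrame(
            columns=[
                "gene", "cell_type", "logFC", "p_value", "adj_pval",
                "n_cells_case", "n_cells_control",
            ]
        )
    return pd.concat(tables, ignore_index=True)


def two_stage_filter(
    cell_table: pd.DataFrame,
    donor_table: pd.DataFrame,
    fdr_cell: float = 0.01,
    fdr_donor: float = 0.05,
) -> pd.DataFrame:
    """Genes significant in a cell-level AND a donor-level table.

    Utility mirroring combinatorial schemes that require a stringent
    cell-level FDR plus a looser donor-level FDR. Joins on
    (gene, cell_type); note that passing both stages does not repair the
    pseudoreplication of the cell-level stage.
    """
    a = cell_table[cell_table["adj_pval"] < fdr_cell]
    b = donor_table[donor_table["adj_pval"] < fdr_donor]
    return a.merge(
        b[["gene", "cell_type"]], on=["gene", "cell_type"], how="inner"
    ).reset_index(drop=True)
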