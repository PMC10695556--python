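"""Donor-level (pseudobulk) differential expression.

Counts are summed over all cells of one donor within one cell type, so each
donor contributes exactly one sample and the test operates at the level of
biological replication. Per gene, a negative-binomial GLM with a log link,

    log mu_s = log(lib_size_s * norm_factor_s) + b0 + b1 * 1[s is case],

is fit by iteratively reweighted least squares, and the condition
coefficient is tested by a likelihood-ratio test against the null model
without ``b1`` (chi-square, 1 df). The NB variance is ``mu + phi * mu^2``;
``phi = 0`` recovers Poisson regression.

Dispersion is estimated per gene by maximizing the Cox-Reid adjusted
profile likelihood over a fixed grid, then shrunk on the log scale toward a
lowess mean-dispersion trend with a fixed prior weight (empirical-Bayes
moderation). This is a deliberately simple stand-in for full quasi/weighted
likelihood machinery; it is documented and configurable.

All per-gene fits are vectorized across genes: the two-column design yields
closed-form 2x2 weighted least-squares solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CellCountMatrix, DonorDesign, PseudobulkMatrix

__all__ = [
    "aggregate",
    "tmm_norm_factors",
    "filter_expressed_pb",
    "bh_adjust",
    "fit_nb_lrt",
    "pseudobulk_de",
    "NBLRTSettings",
]

_LN2 = np.log(2.0)
_POISSON_EPS = 1e-8  # dispersions below this are treated as Poisson


# ---------------------------------------------------------------------------
# aggregation and normalization
# ---------------------------------------------------------------------------

def aggregate(
    matrix: CellCountMatrix,
    design: DonorDesign,
    min_cells: int = 10,
    exclude_doublets: bool = False,
) -> dict:
    """Sum counts per (donor, cell type); one PseudobulkMatrix per type.

    Samples built from fewer than ``min_cells`` cells are dropped (too few
    cells to be a meaningful donor-level measurement). Donors with no cells
    of a type are simply absent from that type's matrix.
    """
    meta = matrix.cell_metadata
    unknown = set(meta["donor_id"]) - set(design.donor_ids)
    if unknown:
        raise ValueError(f"cells reference donors absent from design: {sorted(unknown)}")
    keep = np.ones(len(meta), dtype=bool)
    if exclude_doublets:
        keep &= ~meta["is_doublet"].to_numpy(dtype=bool)

    counts = matrix.counts.tocsc()
    out: dict[str, PseudobulkMatrix] = {}
    for ct in sorted(meta["cell_type"].unique()):
        cols, sample_rows = [], []
        for donor in design.donor_ids:
            sel = (
                (meta["cell_type"] == ct) & (meta["donor_id"] == donor)
            ).to_numpy() & keep
            n = int(sel.sum())
            if n == 0:
                continue
            if n < min_cells:
                continue
            cols.append(np.asarray(counts[:, sel].sum(axis=1)).ravel())
            sample_rows.append({"donor_id": donor, "cell_type": ct, "n_cells": n})
        if not cols:
            continue
        out[ct] = PseudobulkMatrix(
            counts=np.column_stack(cols).astype(np.int64),
            gene_ids=matrix.gene_ids,
            samples=pd.DataFrame(sample_rows),
        )
    return out


def tmm_norm_factors(
    pb: PseudobulkMatrix,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against a reference column, gene-wise log2 ratios (M)
    and average abundances (A) are computed over genes positive in both;
    the most extreme ``logratio_trim`` of M and ``abundance_trim`` of A are
    discarded and the remaining M values averaged with inverse approximate-
    variance weights. Factors are rescaled to geometric mean 1.
    """
    y = np.asarray(pb.counts, dtype=float)
    lib = y.sum(axis=0)
    if (lib > 0).sum() < 2:
        raise ValueError("need at least 2 samples with positive library size")

    # reference: sample whose upper-quartile CPM is closest to the mean
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array(
            [np.quantile(y[:, s] / lib[s], 0.75) if lib[s] > 0 else 0.0
             for s in range(y.shape[1])]
        )
    ref = int(np.argmin(np.abs(uq - uq[uq > 0].mean())))

    factors = np.ones(y.shape[1])
    for s in range(y.shape[1]):
        if lib[s] == 0:
            warnings.warn(
                f"sample {s} has zero library size; norm factor set to 1",
                UserWarning,
                stacklevel=2,
            )
            continue
        if s == ref:
            continue
        factors[s] = _tmm_pair(
            y[:, s], y[:, ref], lib[s], lib[ref], logratio_trim, abundance_trim
        )
    # geometric-mean-1 rescaling
    pos = factors > 0
    factors[pos] /= np.exp(np.mean(np.log(factors[pos])))
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, abundance_trim) -> float:
    both = (obs > 0) & (ref > 0)
    if both.sum() == 0:
        return 1.0
    p_obs, p_ref = obs[both] / n_obs, ref[both] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M
    v = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (
        n_ref * ref[both]
    )
    if np.max(np.abs(m)) < 1e-6:  # columns proportional: no composition shift
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim / 2) + 1, n + 1 - (
        np.floor(n * logratio_trim / 2) + 1
    )
    lo_a, hi_a = np.floor(n * abundance_trim / 2) + 1, n + 1 - (
        np.floor(n * abundance_trim / 2) + 1
    )
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0:
        return 1.0
    w = 1.0 / v[keep]
    return float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))


def filter_expressed_pb(
    pb: PseudobulkMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> np.ndarray:
    """Keep genes with CPM above ``min_cpm`` in at least ``min_samples``
    samples (default: can't be fewer than the smallest comparison group,
    approximated by half the samples when no design is given)."""
    if min_samples is None:
        min_samples = max(2, pb.n_samples // 2)
    lib = np.maximum(pb.lib_size, 1)
    cpm = pb.counts / lib[None, :] * 1e6
    return (cpm > min_cpm).sum(axis=1) >= min_samples


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum() > 0:
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# NB GLM + LRT
# ---------------------------------------------------------------------------

@dataclass
class NBLRTSettings:
    """Tuning of the NB fit; defaults are sensible for tens of samples.

    ``dispersion``: None to estimate; a scalar or per-gene array to fix
    (0 = Poisson). ``prior_df`` is the weight (in effective samples) of the
    mean-dispersion trend when shrinking per-gene estimates.
    """

    dispersion: float | np.ndarray | None = None
    prior_df: float = 10.0
    grid_min: float = 1e-4
    grid_max: float = 20.0
    grid_points: int = 29
    max_iter: int = 50
    tol: float = 1e-10
    use_tmm: bool = True


def _irls_two_group(y, offset, x, phi, max_iter=50, tol=1e-10):
    """Vectorized IRLS for log mu = offset + b0 + b1 * x, per gene.

    y: (G, S) counts; offset: (S,); x: (S,) 0/1; phi: (G,) dispersions.
    Returns b0, b1, mu, converged (each per gene).
    """
    G, S = y.shape
    off = np.exp(offset)[None, :]
    mu = np.maximum(y, 1.0 / 6.0) * 1.0  # positive start
    eta = np.log(mu)
    b1 = np.zeros(G)
    row_mean = np.log(np.maximum(y.sum(axis=1) / off.sum(), 1e-300))
    b0 = row_mean.copy()
    phi_col = phi[:, None]
    converged = np.zeros(G, dtype=bool)
    dev_old = np.full(G, np.inf)
    for _ in range(max_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        np.clip(eta, -300, 300, out=eta)
        mu = np.exp(eta)
        w = mu / (1.0 + phi_col * mu)  # working weights
        z = (eta - offset[None, :]) + (y - mu) / np.maximum(mu, 1e-300)
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swxx = (w * (x**2)[None, :]).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x[None, :] * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        b0_new = (swxx * swz - swx * swxz) / det
        b1_new = (sw * swxz - swx * swz) / det
        dev = _nb_deviance(y, np.exp(
            np.clip(offset[None, :] + b0_new[:, None] + b1_new[:, None] * x[None, :],
                    -300, 300)
        ), phi_col)
        active = ~converged
        b0[active] = b0_new[active]
        b1[active] = b1_new[active]
        newly = active & (np.abs(dev - dev_old) < tol * (np.abs(dev) + 1.0))
        converged |= newly
        dev_old = np.where(active, dev, dev_old)
        if converged.all():
            break
    eta = np.clip(offset[None, :] + b0[:, None] + b1[:, None] * x[None, :], -300, 300)
    mu = np.exp(eta)
    return b0, b1, mu, converged


def _irls_intercept(y, offset, phi, max_iter=50, tol=1e-10):
    """Vectorized IRLS for the intercept-only null model."""
    G, S = y.shape
    phi_col = phi[:, None]
    off = np.exp(offset)[None, :]
    b0 = np.log(np.maximum(y.sum(axis=1) / off.sum(), 1e-300))
    dev_old = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(offset[None, :] + b0[:, None], -300, 300)
        mu = np.exp(eta)
        w = mu / (1.0 + phi_col * mu)
        z = (eta - offset[None, :]) + (y - mu) / np.maximum(mu, 1e-300)
        b0_new = (w * z).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300)
        dev = _nb_deviance(
            y, np.exp(np.clip(offset[None, :] + b0_new[:, None], -300, 300)), phi_col
        )
        active = ~converged
        b0[active] = b0_new[active]
        converged |= active & (np.abs(dev - dev_old) < tol * (np.abs(dev) + 1.0))
        dev_old = np.where(active, dev, dev_old)
        if converged.all():
            break
    eta = np.clip(offset[None, :] + b0[:, None], -300, 300)
    return b0, np.exp(eta), converged


def _nb_deviance(y, mu, phi_col):
    """Unit deviance summed over samples; phi ~ 0 falls back to Poisson."""
    mu = np.maximum(mu, 1e-300)
    pois = phi_col < _POISSON_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
        if np.all(pois):
            dev = 2.0 * (ylogy - (y - mu))
        else:
            phi_safe = np.maximum(phi_col, _POISSON_EPS)
            nb = 2.0 * (
                ylogy
                - (y + 1.0 / phi_safe)
                * np.log((1.0 + phi_safe * y) / (1.0 + phi_safe * mu))
            )
            dev = np.where(pois, 2.0 * (ylogy - (y - mu)), nb)
    return dev.sum(axis=1)


def _nb_loglik(y, mu, phi_col):
    """Full NB log-likelihood (Poisson in the phi -> 0 limit)."""
    mu = np.maximum(mu, 1e-300)
    pois_ll = y * np.log(mu) - mu - special.gammaln(y + 1.0)
    pois = phi_col < _POISSON_EPS
    if np.all(pois):
        return pois_ll.sum(axis=1)
    phi_safe = np.maximum(phi_col, _POISSON_EPS)
    r = 1.0 / phi_safe
    nb_ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(phi_safe * mu)
        - (y + r) * np.log(1.0 + phi_safe * mu)
    )
    return np.where(pois, pois_ll, nb_ll).sum(axis=1)


def _estimate_dispersion(y, offset, x, settings: NBLRTSettings):
    """Grid Cox-Reid APL maximization + lowess-trend shrinkage.

    Returns per-gene shrunk dispersions.
    """
    G, S = y.shape
    grid = np.geomspace(settings.grid_min, settings.grid_max, settings.grid_points)
    apl = np.empty((G, len(grid)))
    for j, phi in enumerate(grid):
        phi_vec = np.full(G, phi)
        b0, b1, mu, _ = _irls_two_group(y, offset, x, phi_vec, max_iter=25)
        ll = _nb_loglik(y, mu, phi_vec[:, None])
        # Cox-Reid adjustment: -0.5 log det of the 2x2 Fisher information
        w = mu / (1.0 + phi * mu)
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swxx = (w * (x**2)[None, :]).sum(axis=1)
        det = np.maximum(sw * swxx - swx**2, 1e-300)
        apl[:, j] = ll - 0.5 * np.log(det)
    mle = grid[np.argmax(apl, axis=1)]

    # lowess trend of log dispersion against average log CPM
    lib = np.exp(offset)
    ave_logcpm = np.log2((y + 0.5) / (lib[None, :] + 1.0) * 1e6).mean(axis=1)
    log_mle = np.log(mle)
    if G >= 10:
        order = np.argsort(ave_logcpm)
        sm = lowess(
            log_mle[order], ave_logcpm[order], frac=0.4, it=1, return_sorted=False
        )
        trend = np.empty(G)
        trend[order] = sm
    else:
        trend = np.full(G, log_mle.mean())
    df_resid = max(S - 2, 1)
    log_shrunk = (df_resid * log_mle + settings.prior_df * trend) / (
        df_resid + settings.prior_df
    )
    return np.clip(np.exp(log_shrunk), settings.grid_min, settings.grid_max)


def fit_nb_lrt(
    pb: PseudobulkMatrix,
    design: DonorDesign,
    settings: NBLRTSettings | None = None,
) -> pd.DataFrame:
    """Per-gene NB GLM + likelihood-ratio test of the condition effect.

    Returns a DEG table with columns ``gene``, ``cell_type``, ``logFC``
    (log2), ``logCPM``, ``LR``, ``p_value``, ``adj_pval`` (BH within this
    table), ``converged``. Genes whose fits did not converge carry NaN
    statistics.
    """
    settings = settings or NBLRTSettings()
    samples = pb.samples
    cond = design.condition
    x = (
        samples["donor_id"].map(cond).eq("case").to_numpy(dtype=float)
    )
    n_case, n_ctrl = int(x.sum()), int((1 - x).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError(
            f"need >= 2 donors per condition, got {n_case} case / {n_ctrl} control"
        )

    y = np.asarray(pb.counts, dtype=float)
    lib = np.maximum(pb.lib_size.astype(float), 1.0)
    factors = tmm_norm_factors(pb) if settings.use_tmm else np.ones(len(lib))
    offset = np.log(lib * factors)

    nonzero = y.sum(axis=1) > 0
    yk = y[nonzero]
    G = yk.shape[0]

    if settings.dispersion is None:
        phi = _estimate_dispersion(yk, offset, x, settings)
    else:
        phi = np.broadcast_to(
            np.asarray(settings.dispersion, dtype=float), (y.shape[0],)
        )[nonzero].copy()

    b0f, b1f, mu_full, conv_f = _irls_two_group(
        yk, offset, x, phi, settings.max_iter, settings.tol
    )
    b0n, mu_null, conv_n = _irls_intercept(
        yk, offset, phi, settings.max_iter, settings.tol
    )
    phi_col = phi[:, None]
    lr = _nb_deviance(yk, mu_null, phi_col) - _nb_deviance(yk, mu_full, phi_col)
    lr = np.maximum(lr, 0.0)
    converged = conv_f & conv_n
    p = stats.chi2.sf(lr, df=1)
    logfc = b1f / _LN2
    logcpm = np.log2((yk + 0.5) / ((lib * factors)[None, :] + 1.0) * 1e6).mean(axis=1)

    lr = np.where(converged, lr, np.nan)
    p = np.where(converged, p, np.nan)
    logfc = np.where(converged, logfc, np.nan)

    cell_type = samples["cell_type"].iloc[0] if len(samples) else ""
    table = pd.DataFrame(
        {
            "gene": pb.gene_ids[nonzero],
            "cell_type": cell_type,
            "logFC": logfc,
            "logCPM": logcpm,
            "LR": lr,
            "p_value": p,
            "adj_pval": bh_adjust(p),
            "converged": converged,
        }
    )
    return table


def pseudobulk_de(
    matrix: CellCountMatrix,
    design: DonorDesign,
    min_cells: int = 10,
    min_cpm: float = 1.0,
    settings: NBLRTSettings | None = None,
    adjust_globally: bool = False,
) -> pd.DataFrame:
    """Full pseudobulk pipeline over every cell type.

    Aggregates, filters lowly expressed genes per cell type, fits the
    NB LRT, and BH-adjusts within each cell type (or globally when
    ``adjust_globally``). Returns the concatenated DEG table.
    """
    pbs = aggregate(matrix, design, min_cells=min_cells)
    tables = []
    for ct, pb in pbs.items():
        cond = design.condition
        grp = pb.samples["donor_id"].map(cond)
        n_case, n_ctrl = (grp == "case").sum(), (grp == "control").sum()
        if n_case < 2 or n_ctrl < 2:
            continue
        mask = filter_expressed_pb(pb, min_cpm=min_cpm, min_samples=min(n_case, n_ctrl))
        if mask.sum() == 0:
            continue
        sub = PseudobulkMatrix(
            counts=pb.counts[mask],
            gene_ids=pb.gene_ids[mask],
            samples=pb.samples,
        )
        tables.append(fit_nb_lrt(sub, design, settings))
    if not tables:
        return pd.DataFrame(
            columns=[
                "gene", "cell_type", "logFC", "logCPM", "LR",
                "p_value", "adj_pval", "converged",
            ]
        )
    out = pd.concat(tables, ignore_index=True)
    if adjust_globally:
        out["adj_pval"] = bh_adjust(out["p_value"].to_numpy())
    return out
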