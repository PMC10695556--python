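"""Hierarchical single-nucleus count simulator.

The generator emits gene x cell counts with the dependence structure that
makes cell-level ("pseudoreplication") differential expression misleading:
cells are nested inside donors, and each gene carries a donor-specific
random effect on the log scale, so expression of two cells from the same
donor is positively correlated while donors themselves are exchangeable.
Treating cells as independent replicates then overstates the effective
sample size in proportion to the number of cells per donor.

Model for the count of gene ``g`` in cell ``c`` of type ``t`` from donor
``d``::

    count ~ NB(mean = s_c * exp(log mu_gt + u_gd + beta_gt * case_d),
               dispersion = phi_g)

with ``u_gd ~ Normal(0, donor_sd^2)`` (gene-by-donor effect), ``s_c`` a
log-normal cell size factor, ``beta_gt`` a +/- de_lfc * ln(2) condition
effect on truly DE genes, and NB variance ``mu + phi * mu^2`` (gamma-Poisson
mixture; ``phi = 0`` gives the Poisson limit).

On top of the clean counts the generator plants the two QC artifacts the
filtering cascade is meant to catch: "dying" cells whose counts are
redistributed onto mitochondrial genes so their mitochondrial fraction
follows a Beta law, and doublet barcodes formed by summing two cells from
the same donor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellCountMatrix, DonorDesign

__all__ = ["SimulationParams", "GroundTruth", "generate_dataset"]

#: cells per donor by type; roughly cortex-like, a 10:1 spread between the
#: most abundant (excitatory neurons) and rarest (microglia) types
DEFAULT_CELL_TYPE_PROFILE = {
    "Exc": 200,
    "Oligo": 100,
    "Astro": 60,
    "Inh": 50,
    "OPC": 30,
    "Micro": 20,
}


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults give a cortex-like 24+24 cohort.

    ``de_lfc`` is a log2 fold-change magnitude; its sign is randomized per
    (gene, cell type). ``dispersion`` may be a scalar applied to every gene
    or a length-``n_genes`` array; 0 means Poisson. ``donor_sd`` is the
    standard deviation of the gene-by-donor random effect on the natural-log
    scale — 0.3 corresponds to a ~30% coefficient of variation in a gene's
    donor-level expected expression, a moderate level of biological
    between-replicate variability.
    """

    n_case: int = 24
    n_control: int = 24
    cell_type_profile: dict = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPE_PROFILE)
    )
    n_genes: int = 2000
    baseline_log_mean: float = -0.7
    baseline_log_sd: float = 1.0
    dispersion: float | np.ndarray = 0.5
    donor_sd: float = 0.3
    de_fraction: float = 0.05
    de_lfc: float = 1.0
    libsize_sd: float = 0.3
    mito_gene_fraction: float = 0.01
    dying_cell_fraction: float = 0.1
    dying_mito_beta: tuple = (8.0, 2.0)
    doublet_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_genes"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            setattr(self, name, int(v))
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 donors per condition")
        for name in (
            "de_fraction",
            "mito_gene_fraction",
            "dying_cell_fraction",
            "doublet_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        phi = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if np.any(phi < 0):
            raise ValueError("dispersion must be >= 0 (0 = Poisson limit)")
        if not self.cell_type_profile or min(self.cell_type_profile.values()) < 1:
            raise ValueError("cell_type_profile values must be >= 1")
        if self.libsize_sd < 0 or self.donor_sd < 0:
            raise ValueError("donor_sd and libsize_sd must be >= 0")

    @property
    def cell_types(self) -> list:
        return list(self.cell_type_profile)

    @property
    def donor_ids(self) -> list:
        return [f"case_{i + 1:02d}" for i in range(self.n_case)] + [
            f"ctrl_{i + 1:02d}" for i in range(self.n_control)
        ]


@dataclass
class GroundTruth:
    """Which (gene, cell type) pairs are truly DE and at what log2 FC."""

    table: pd.DataFrame  # columns: gene, cell_type, is_de, true_lfc

    def de_genes(self, cell_type: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["is_de"]]
        if cell_type is not None:
            t = t[t["cell_type"] == cell_type]
        return t.reset_index(drop=True)


def _gene_dispersions(params: SimulationParams) -> np.ndarray:
    phi = np.asarray(params.dispersion, dtype=float)
    if phi.ndim == 0:
        return np.full(params.n_genes, float(phi))
    if phi.shape != (params.n_genes,):
        raise ValueError("per-gene dispersion must have length n_genes")
    return phi


def _draw_ground_truth(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """DE flags drawn independently per cell type, Rademacher signs."""
    n_de = int(round(params.de_fraction * params.n_genes))
    if params.de_fraction > 0 and params.de_lfc != 0 and n_de < 1:
        warnings.warn(
            "de_fraction * n_genes < 1: emitting zero truly DE genes",
            UserWarning,
            stacklevel=3,
        )
        n_de = 0
    gene_names = _gene_names(params)
    rows = []
    beta_nat = {}  # cell_type -> per-gene natural-log condition coefficient
    ln2 = np.log(2.0)
    for ct in params.cell_types:
        lfc = np.zeros(params.n_genes)
        if n_de > 0 and params.de_lfc != 0:
            idx = rng.choice(params.n_genes, size=n_de, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            lfc[idx] = signs * params.de_lfc
        beta_nat[ct] = lfc * ln2
        rows.append(
            pd.DataFrame(
                {
                    "gene": gene_names,
                    "cell_type": ct,
                    "is_de": lfc != 0,
                    "true_lfc": lfc,
                }
            )
        )
    return pd.concat(rows, ignore_index=True), beta_nat


def _gene_names(params: SimulationParams) -> np.ndarray:
    """Mitochondrial genes carry the conventional ``MT-`` prefix."""
    n_mito = int(round(params.mito_gene_fraction * params.n_genes))
    names = [f"MT-G{i + 1:04d}" for i in range(n_mito)]
    names += [f"G{i + 1:04d}" for i in range(n_mito, params.n_genes)]
    return np.asarray(names, dtype=object)


def _sample_nb(
    mean: np.ndarray, phi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw with per-gene dispersion; phi=0 rows are Poisson."""
    lam = np.array(mean, dtype=float)
    over = phi > 0
    if np.any(over):
        shape = 1.0 / phi[over]
        lam[over] = rng.gamma(
            shape[:, None], mean[over] * phi[over][:, None]
        )
    return rng.poisson(lam).astype(np.int32)


def _redistribute_dying(
    block: np.ndarray,
    dying_cols: np.ndarray,
    mito_idx: np.ndarray,
    mito_weights: np.ndarray,
    beta_ab: tuple,
    rng: np.random.Generator,
) -> None:
    """Push a Beta-distributed share of each dying cell's counts onto
    mitochondrial genes, holding the cell's total fixed."""
    non_mito = np.setdiff1d(np.arange(block.shape[0]), mito_idx)
    for c in dying_cols:
        total = int(block[:, c].sum())
        if total == 0:
            continue
        p = rng.beta(*beta_ab)
        m = rng.binomial(total, p)
        new_col = np.zeros(block.shape[0], dtype=np.int32)
        if m > 0:
            new_col[mito_idx] = rng.multinomial(m, mito_weights)
        if total - m > 0:
            w = block[non_mito, c].astype(float)
            if w.sum() == 0:
                w = np.ones(len(non_mito))
            new_col[non_mito] = rng.multinomial(total - m, w / w.sum())
        block[:, c] = new_col


def generate_dataset(
    params: SimulationParams,
) -> tuple[CellCountMatrix, DonorDesign, GroundTruth]:
    """Simulate a full case/control cohort.

    Returns the emitted count matrix (doublet barcodes included and
    flagged), the donor design table, and the ground-truth DE table.
    Identical parameters and seed give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    phi = _gene_dispersions(params)
    gene_names = _gene_names(params)
    n_mito = int(np.char.startswith(gene_names.astype(str), "MT-").sum())
    mito_idx = np.arange(n_mito)

    truth_table, beta_nat = _draw_ground_truth(params, rng)

    # per-gene, per-cell-type baseline means (log-normal)
    log_mu = {
        ct: rng.normal(params.baseline_log_mean, params.baseline_log_sd, params.n_genes)
        for ct in params.cell_types
    }

    donor_ids = params.donor_ids
    is_case = np.array([d.startswith("case") for d in donor_ids])

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[pd.DataFrame] = []
    for d_i, donor in enumerate(donor_ids):
        # gene-by-donor random effects (shared by all that donor's cells)
        u = rng.normal(0.0, params.donor_sd, size=(params.n_genes,))
        n_per_type = {
            ct: max(1, rng.poisson(lam))
            for ct, lam in params.cell_type_profile.items()
        }
        n_cells = sum(n_per_type.values())
        size_factors = rng.lognormal(
            -0.5 * params.libsize_sd**2, params.libsize_sd, n_cells
        )
        log_mean = np.empty((params.n_genes, n_cells))
        types = np.empty(n_cells, dtype=object)
        col = 0
        for ct, n_ct in n_per_type.items():
            eta = log_mu[ct] + u
            if is_case[d_i]:
                eta = eta + beta_nat[ct]
            log_mean[:, col : col + n_ct] = eta[:, None]
            types[col : col + n_ct] = ct
            col += n_ct
        mean = np.exp(log_mean) * size_factors[None, :]
        block = _sample_nb(mean, phi, rng)

        # dying cells: mitochondrial fraction pushed up to a Beta(a, b) draw
        n_dying = int(round(params.dying_cell_fraction * n_cells))
        dying = np.zeros(n_cells, dtype=bool)
        if n_dying > 0 and n_mito > 0:
            dying_cols = rng.choice(n_cells, size=n_dying, replace=False)
            dying[dying_cols] = True
            # weight mito genes by their donor-level expected expression
            mito_w = np.exp(log_mu[params.cell_types[0]][mito_idx] + u[mito_idx])
            mito_w = mito_w / mito_w.sum()
            _redistribute_dying(
                block, dying_cols, mito_idx, mito_w, params.dying_mito_beta, rng
            )

        # doublets: pairs of same-donor cells collapse into one barcode
        n_doub = int(round(params.doublet_rate * n_cells))
        n_doub = min(n_doub, n_cells // 2)
        keep = np.ones(n_cells, dtype=bool)
        doublet_cols = []
        doublet_types = []
        if n_doub > 0:
            members = rng.choice(n_cells, size=2 * n_doub, replace=False)
            keep[members] = False
            for a, b in members.reshape(-1, 2):
                doublet_cols.append(block[:, a] + block[:, b])
                doublet_types.append(types[a])
        emitted = block[:, keep]
        emitted_types = list(types[keep])
        emitted_dying = list(dying[keep])
        if doublet_cols:
            emitted = np.hstack([emitted, np.column_stack(doublet_cols)])
            emitted_types += doublet_types
            emitted_dying += [False] * n_doub
        n_emitted = emitted.shape[1]
        blocks.append(sp.csr_matrix(emitted))
        meta_rows.append(
            pd.DataFrame(
                {
                    "barcode": [f"{donor}:BC{j + 1:05d}" for j in range(n_emitted)],
                    "donor_id": donor,
                    "cell_type": emitted_types,
                    "is_doublet": [False] * (n_emitted - n_doub) + [True] * n_doub,
                    "is_dying": emitted_dying,
                }
            )
        )

    matrix = CellCountMatrix(
        counts=sp.hstack(blocks, format="csr"),
        gene_ids=gene_names,
        cell_metadata=pd.concat(meta_rows, ignore_index=True),
    )
    design = DonorDesign(
        pd.DataFrame(
            {
                "donor_id": donor_ids,
                "condition": np.where(is_case, "case", "control"),
            }
        )
    )
    return matrix, design, GroundTruth(truth_table)
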