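# Methods

## The problem being modelled

Case/control single-nucleus RNA-seq experiments sample two levels of
variation: biological variation between donors, and measurement/cellular
variation between nuclei within a donor. Any test whose unit of analysis
is the nucleus implicitly assumes the second level is all there is. When
donors differ — and they always do — per-cell tests ("pseudoreplication")
treat thousands of correlated observations as independent evidence, and
their false-discovery count scales with cell abundance rather than donor
count. The package provides both procedures, a simulator whose dependence
structure makes the failure visible, and a donor-label permutation
benchmark that measures it.

## Simulator

The count of gene *g* in cell *c* of type *t* from donor *d* is

    y_gc ~ NB(mean = s_c · exp(log μ_gt + u_gd + β_gt · 1[d is case]),
              dispersion = φ_g)

- **Baselines** log μ_gt are drawn i.i.d. Normal(`baseline_log_mean`,
  `baseline_log_sd²`) per gene and cell type (defaults −0.7 and 1.0,
  giving a median expected count just under one per gene per cell and a
  realistically long-tailed expression distribution; with 2,000 genes this
  yields libraries of a few thousand counts, typical of nuclei).
- **Donor effects** u_gd ~ Normal(0, `donor_sd`²) are drawn per gene ×
  donor, *not* per donor globally: a donor-global scalar would shift every
  gene equally and be absorbed by library-size normalization, leaving
  nothing for pseudoreplication to exploit. Per-gene effects survive
  normalization, which is exactly the situation in real data. The default
  `donor_sd = 0.3` (natural-log scale, ≈ 30% CV in donor-level expected
  expression; donor-level NB dispersion ≈ exp(σ²)−1 ≈ 0.09) was chosen
  once as a moderate, realistic level of between-replicate biological
  variability — strong enough that cell-level inflation is unmistakable,
  mild enough that donor-level analysis retains power.
- **Dispersion** φ (default 0.5, scalar or per-gene) is the NB
  overdispersion of single-nucleus counts; 0 gives the Poisson limit.
  Sampling is gamma–Poisson.
- **True DE**: a fraction `de_fraction` of genes per cell type (chosen
  independently per type) receives a condition coefficient of magnitude
  `de_lfc` log2 units with Rademacher sign — published DEG tables show
  both directions in comparable numbers.
- **Size factors** s_c are log-normal with log-sd `libsize_sd` (default
  0.3) and unit mean.
- **Dying cells**: a fraction (default 0.1) of cells have their total
  count redistributed so that the mitochondrial share follows
  Beta(8, 2) (mean 0.8) — cells losing cytoplasmic RNA while retaining
  mitochondria. Totals are preserved; the mitochondrial part is spread
  over MT- genes by expected expression, the remainder over the cell's
  other genes proportionally to its existing counts.
- **Doublets**: a fraction (default 0.05) of emitted barcodes are
  element-wise sums of two cells drawn uniformly at random from the same
  donor (droplet doublets are within-sample events); the merged cells are
  removed, the doublet carries the first member's cell-type label and an
  `is_doublet` flag.
- Mitochondrial genes are named with the human `MT-` prefix (default 1%
  of genes), which the QC module keys on.
- One `numpy` Generator seeded by the single user seed drives everything;
  identical parameters give bit-identical output.

What the generator does **not** emulate: ambient RNA/empty droplets (cells
arrive already called), gene–gene correlation networks, batch effects
between samples, cell-type-specific library sizes, or realistic marker
structure. A green test on synthetic data therefore establishes the
*statistical* behaviour of the procedures under hierarchical dependence,
not their behaviour under every artefact of real data.

## QC cascade

Per cell: library size ≥ 200; expressed genes ≥ 200; library size and
expressed genes each ≤ median + 4·MAD (upper tail only — the lower tail is
governed by the fixed minimums); mitochondrial fraction < 0.10; not a
flagged doublet. "Expressed genes" counts only genes with ≥ 2 counts in
≥ 3 cells of the full pre-QC matrix; the mask is computed once
(single-pass), then per-cell expressed-gene counts are taken over
masked-in genes, while mitochondrial fractions use all genes (they are a
property of the library's composition). The mitochondrial criterion fires
at ≥ 0.10 by default (`mito_strict=True` switches to > 0.10; operational
records of such cascades count the boundary as failing). The MAD carries
no 1.4826 normal-consistency constant by default ("4 MAD" means four raw
median absolute deviations; configurable). A zero MAD yields a +inf
threshold and a warning rather than flagging everything at the median.
Doublet *detection* is out of scope — QC consumes the metadata flag.

Accounting: per-criterion failure counts overlap (a cell can fail
several), so only total-failed + total-passed is guaranteed to equal the
input cell count; the report table states both.

## Pseudobulk DE

Counts are summed over all cells of a (donor, cell type) pair; samples
with fewer than 10 cells (configurable) are dropped as too thin to be a
donor-level measurement. Library sizes are column sums; TMM normalization
factors are computed per cell type (30% two-sided trim on log-ratios, 5%
on abundance, inverse-delta-method-variance weights, geometric mean 1;
reference = sample with the most typical upper-quartile CPM). Genes need
CPM > 1 in at least `min(group sizes)` samples.

Per gene, the NB GLM `log μ = offset(log N·f) + β₀ + β₁·1[case]` is fit by
IRLS, vectorized across genes (a two-column design gives closed-form 2×2
weighted least-squares solves). The LRT statistic is the deviance
difference against the intercept-only fit, referred to χ²(1); `logFC` is
β₁/ln 2; `logCPM` is the across-sample mean of log2((y+0.5)/(N·f+1)·10⁶).
BH adjustment is applied within each cell type (Table-style per-cell-type
reporting; a flag switches to global adjustment).

**Dispersion.** For each gene the Cox–Reid adjusted profile likelihood
(log-likelihood minus ½ log det of the 2×2 Fisher information) is
maximized over a 29-point geometric grid on [1e-4, 20]; the per-gene
maximizer is then shrunk on the log scale toward a lowess trend of log
dispersion against average logCPM, with the trend given a fixed prior
weight of 10 effective samples against the gene's residual df. This is a
deliberately simple moderation scheme: it reproduces the qualitative
behaviour of weighted-likelihood empirical Bayes without its machinery,
and both the grid and the prior weight are configurable. Fixing
`dispersion=0` turns the engine into exact Poisson regression (used by the
oracle tests). Non-converged fits (rare, near-degenerate genes) are
flagged and carry NaN statistics.

Calibration measured on the simulator: with independent cells
(`donor_sd=0`) the raw false-positive rate at p < 0.05 is ≈ 0.06; with
`donor_sd=0.3` the extreme tail is mildly inflated (≈ 2–3× at p < 0.001)
because the donor effects are log-normal while the NB assumes gamma
mixing, and the χ² reference is asymptotic in the number of donors —
after BH at FDR 0.05 this still leaves a median of zero discoveries per
cell type under permuted labels.

## Cell-level DE

Each cell is normalized to counts-per-ten-thousand and log1p-transformed
(the transformation is configurable back to raw counts; published
cell-level analyses rarely state theirs, so a standard one was chosen and
documented rather than guessed). Per gene, a two-sided Wilcoxon rank-sum
test compares case and control cells: mid-rank ties, normal approximation
with tie-corrected variance and continuity correction, switching to exact
enumeration of rank assignments when both groups have ≤ 8 observations
(cost C(n₁+n₂, n₁); beyond that the asymptotic p is accurate and
enumeration is pointless). logFC is log2 of the ratio of group means of
normalized expression with a 1e-9 pseudo-count; BH within cell type. A
gene constant across all cells gets p = 1 and logFC = 0.

The two-stage "significant at strict cell-level FDR *and* looser
donor-level FDR" rule that some studies apply is provided only as a filter
utility over two DEG tables (`two_stage_filter`); the mixed-model
donor-level stage it was historically paired with is out of scope, and the
utility's docstring notes that passing both stages does not repair the
cell-level stage's pseudoreplication.

## Permutation benchmark

Condition labels are permuted uniformly at random over donors — never over
cells, because cell-level shuffling would destroy the within-donor
dependence that is the object of study — preserving group sizes exactly.
Permutation 0 is the observed labelling, so the benchmark subsumes the
primary analysis; permutation *i* uses seed `base_seed + i` so any single
permutation is reproducible in isolation. For each permutation and method
the benchmark records the per-cell-type count of genes with BH-adjusted
p below the FDR cut-off, alongside post-QC cell counts. Covariates are not
constrained in the permutation (none are modelled). A method failing on
one permutation is recorded as missing rather than aborting the run.

DEG counts are summarized per (permutation, cell type) — the same unit the
DEG-count/cell-count correlation diagnostic is computed on (six cell types
per permutation), so "median DEG count" means the median of those
per-cell-type counts.

## Diagnostics and fixtures

`deg_summary` filters a DEG table at an FDR cut-off and reports the number
of distinct gene symbols ("unique DEGs" — distinct symbols across cell
types), the median absolute log2 FC and median adjusted p (midpoint
convention for even lengths), and per-cell-type row percentages rounded to
integers. `deg_cellcount_correlation` is the sample Pearson correlation
between per-cell-type DEG counts and cell counts (≥ 3 cell types; NaN
with a warning when either vector is constant). `compare_fold_changes`
inner-joins two tables on (gene, cell type), restricted to rows
significant in the second table, and correlates the paired log2 FCs (NaN
below 3 joined rows). Two published DEG tables ship as verbatim TSV
fixtures with frozen sha256 checksums; the join key across tables is the
gene symbol, with Ensembl ids preserved as an auxiliary column where
printed.

## Numerical choices and degenerate inputs

- IRLS: deviance-change convergence at 1e-10 relative, 50 iterations,
  linear predictors clipped to ±300 to avoid overflow; non-convergence is
  reported, not raised.
- LR statistics are clamped at 0 (tiny negative values are round-off).
- Zero-library samples get TMM factor 1 with a warning; all-zero genes
  are excluded before fitting; an all-zero cell has mitochondrial
  fraction defined as 0 with an explicit degenerate flag.
- MatrixMarket files are 1-based coordinate integer on disk, 0-based in
  memory; the conversion is confined to `snde.io`.

## Known limitations

- The dispersion moderation is a simplification of production empirical-
  Bayes machinery; its extreme-tail calibration under heavy-tailed donor
  effects is mildly liberal (quantified above).
- Quasi-likelihood F-tests, mixed models and covariate adjustment beyond
  the condition term are deliberately out of scope.
- The simulator's QC artifacts are stylized; it validates the filtering
  logic, not the biology of cell death or doublet formation.
- Exact rank-sum enumeration is limited to groups of ≤ 8; at realistic
  cell numbers only the asymptotic path runs.
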