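"""QC cascade: metrics, expressed-gene mask, MAD thresholds, accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snde.qc import (
    QCThresholds,
    apply_qc,
    compute_cell_qc,
    expressed_gene_mask,
    mad_upper_threshold,
    run_qc,
)

from conftest import make_matrix


class TestCellMetrics:
    def test_arithmetic_example(self):
        # one cell: MT gene 10 counts, other gene 90 -> mito fraction 0.10
        m = make_matrix([[10], [90]], gene_ids=["MT-A", "B"])
        met = compute_cell_qc(m)
        assert met.total_counts[0] == 100
        assert met.n_expressed_genes[0] == 2
        assert met.mito_fraction[0] == pytest.approx(0.10)

    def test_all_zero_cell_degenerate(self):
        m = make_matrix([[0, 5], [0, 5]], gene_ids=["MT-A", "B"])
        met = compute_cell_qc(m)
        assert met.total_counts[0] == 0
        assert met.mito_fraction[0] == 0.0
        assert met.zero_total[0] and not met.zero_total[1]

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(1.0, size=(50, 20))
        gene_ids = [f"MT-{i}" if i < 5 else f"G{i}" for i in range(50)]
        m = make_matrix(dense, gene_ids=gene_ids)
        met = compute_cell_qc(m)
        np.testing.assert_array_equal(met.total_counts, dense.sum(axis=0))
        np.testing.assert_array_equal(met.n_expressed_genes, (dense > 0).sum(axis=0))
        tot = dense.sum(axis=0)
        expected = np.where(tot > 0, dense[:5].sum(axis=0) / np.maximum(tot, 1), 0)
        np.testing.assert_allclose(met.mito_fraction, expected)

    def test_unknown_mito_ids_error(self):
        m = make_matrix([[1], [2]], gene_ids=["A", "B"])
        with pytest.raises(ValueError, match="NOPE"):
            compute_cell_qc(m, mito_gene_ids=["A", "NOPE"])


class TestExpressedGeneMask:
    @pytest.mark.parametrize(
        "counts, kept",
        [
            ([2, 2, 2, 0], True),  # three cells reach 2 counts
            ([1, 1, 1, 1], False),  # no cell reaches 2
            ([5, 0, 0, 0], False),  # only one qualifying cell
        ],
    )
    def test_definition(self, counts, kept):
        m = make_matrix([counts])
        assert expressed_gene_mask(m)[0] == kept

    def test_threshold_validation(self):
        m = make_matrix([[1, 2]])
        with pytest.raises(ValueError):
            expressed_gene_mask(m, min_counts=0)


class TestMADThreshold:
    def test_hand_computed_example(self):
        # median 3, MAD 1 -> threshold 3 + 4*1 = 7; 100 is above it
        assert mad_upper_threshold([1, 2, 3, 4, 100]) == pytest.approx(7.0)

    def test_constant_vector_warns_inf(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            assert mad_upper_threshold([5, 5, 5]) == np.inf

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=30,
        ),
        n1=st.floats(min_value=0.1, max_value=10),
        n2=st.floats(min_value=0.1, max_value=10),
    )
    def test_monotone_in_n_mads(self, values, n1, n2):
        import warnings

        lo, hi = sorted([n1, n2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert mad_upper_threshold(values, lo) <= mad_upper_threshold(values, hi)


class TestApplyQC:
    def _metrics_five_cells(self):
        # cell 0: fails library min only; cell 1: fails library min AND mito;
        # cells 2-4 clean
        genes = ["MT-A"] + [f"G{i}" for i in range(9)]
        dense = np.zeros((10, 5), dtype=int)
        dense[1:, 0] = [11] + [0] * 8  # cell 0: total 11 < 200
        dense[0, 1] = 50  # cell 1: total 50, mito 100%
        for c in (2, 3, 4):
            dense[1:, c] = 60 + c  # totals ~550, 9 expressed genes
        m = make_matrix(dense, gene_ids=genes)
        return compute_cell_qc(m)

    def test_union_accounting_on_fixture(self):
        met = self._metrics_five_cells()
        thr = QCThresholds(min_library_size=200, min_expressed_genes=5,
                           mad_multiplier=100)
        res = apply_qc(met, thr)
        assert res.flags["min_library_size"].sum() == 2
        assert res.flags["mito_fraction"].sum() == 1
        # union, not sum: cell 1 fails both criteria
        assert res.n_failed == 2
        assert res.n_passed + res.n_failed == 5
        summary = res.summary.set_index("criterion")["cells"]
        assert summary["total_failed"] == 2
        assert summary["total_passed"] == 3

    def test_all_pass_identity(self):
        rng = np.random.default_rng(1)
        dense = rng.poisson(5, size=(300, 10)) + 1
        m = make_matrix(dense, gene_ids=[f"G{i}" for i in range(300)])
        met = compute_cell_qc(m)
        res = apply_qc(met, QCThresholds(mad_multiplier=50))
        assert res.n_passed == 10

    def test_raising_mito_max_never_decreases_passed(self):
        met = self._metrics_five_cells()
        passed = [
            apply_qc(met, QCThresholds(mito_max=mx, mad_multiplier=100)).n_passed
            for mx in (0.05, 0.10, 0.5, 1.0)
        ]
        assert passed == sorted(passed)

    def test_empty_input(self):
        m = make_matrix(np.zeros((3, 0), dtype=int))
        res = apply_qc(compute_cell_qc(m), QCThresholds())
        assert res.n_passed == 0 and res.n_failed == 0
        assert res.summary.set_index("criterion")["cells"]["total_passed"] == 0


def test_mito_criterion_catches_dying_cells(small_cohort):
    """Dying cells get Beta(8,2)-distributed mitochondrial fractions, far
    above the 0.1 cut-off, so nearly all should be flagged."""
    _, matrix, _, _ = small_cohort
    met = compute_cell_qc(matrix)
    res = apply_qc(met, QCThresholds())
    dying = matrix.cell_metadata["is_dying"].to_numpy()
    assert dying.sum() >= 20
    caught = res.flags["mito_fraction"].to_numpy()[dying]
    assert caught.mean() >= 0.95


def test_run_qc_accounting_identity(small_cohort):
    _, matrix, _, _ = small_cohort
    filtered, res, gene_mask = run_qc(
        matrix, QCThresholds(min_library_size=50, min_expressed_genes=50)
    )
    assert res.n_passed + res.n_failed == matrix.n_cells
    assert filtered.n_cells == res.n_passed
    assert filtered.n_genes == gene_mask.sum()
    # union bound
    per_criterion = res.summary.set_index("criterion")["cells"]
    crit_sum = per_criterion.drop(["pre_qc", "total_failed", "total_passed"]).sum()
    assert res.n_failed <= crit_sum
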