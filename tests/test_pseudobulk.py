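"""Pseudobulk DE: aggregation, TMM, BH, NB-GLM likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snde.containers import DonorDesign, PseudobulkMatrix
from snde.pseudobulk import (
    NBLRTSettings,
    aggregate,
    bh_adjust,
    filter_expressed_pb,
    fit_nb_lrt,
    tmm_norm_factors,
)

from conftest import make_design, make_matrix


def _pb(counts, conditions):
    counts = np.asarray(counts)
    donors = [f"D{j}" for j in range(counts.shape[1])]
    pb = PseudobulkMatrix(
        counts=counts,
        gene_ids=[f"G{i}" for i in range(counts.shape[0])],
        samples=pd.DataFrame(
            {"donor_id": donors, "cell_type": "T", "n_cells": 100}
        ),
    )
    design = make_design(dict(zip(donors, conditions)))
    return pb, design


class TestAggregate:
    def test_simple_sum(self):
        dense = [[1, 2, 3], [0, 1, 0]]
        m = make_matrix(dense, donors=["A", "A", "A"], cell_types=["T"] * 3)
        design = make_design({"A": "case", "B": "control"})
        pb = aggregate(m, design, min_cells=1)["T"]
        np.testing.assert_array_equal(pb.counts[:, 0], [6, 1])

    def test_matches_dense_groupby_oracle(self):
        rng = np.random.default_rng(2)
        dense = rng.poisson(2, size=(100, 120))
        donors = rng.choice(["A", "B", "C", "D"], size=120)
        types = rng.choice(["T1", "T2"], size=120)
        m = make_matrix(dense, donors=donors, cell_types=types)
        design = make_design(
            {"A": "case", "B": "case", "C": "control", "D": "control"}
        )
        pbs = aggregate(m, design, min_cells=1)
        for ct, pb in pbs.items():
            for j, row in pb.samples.iterrows():
                sel = (donors == row.donor_id) & (types == ct)
                np.testing.assert_array_equal(pb.counts[:, j], dense[:, sel].sum(axis=1))
                assert row.n_cells == sel.sum()
        # conservation: pseudobulk totals = input totals
        total = sum(pb.counts.sum() for pb in pbs.values())
        assert total == dense.sum()

    def test_min_cells_drops_small_samples(self):
        dense = np.ones((5, 12), dtype=int)
        donors = ["A"] * 10 + ["B"] * 2
        m = make_matrix(dense, donors=donors)
        design = make_design({"A": "case", "B": "control"})
        pb = aggregate(m, design, min_cells=5)["T"]
        assert list(pb.samples.donor_id) == ["A"]

    def test_unknown_donor_errors(self):
        m = make_matrix([[1]], donors=["X"])
        design = make_design({"A": "case", "B": "control"})
        with pytest.raises(ValueError, match="absent from design"):
            aggregate(m, design)


class TestTMM:
    def test_identical_columns_unity(self):
        y = np.tile(np.arange(1, 101)[:, None], (1, 4))
        pb, _ = _pb(y, ["case"] * 2 + ["control"] * 2)
        np.testing.assert_allclose(tmm_norm_factors(pb), 1.0)

    def test_pure_depth_change_unity(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(50, size=(500, 1))
        y = np.hstack([base, base * 2, base, base])
        pb, _ = _pb(y, ["case"] * 2 + ["control"] * 2)
        np.testing.assert_allclose(tmm_norm_factors(pb), 1.0, atol=1e-6)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(6)
        y = rng.poisson(rng.uniform(1, 50, size=(200, 1)), size=(200, 6))
        y[:50, 0] *= 5  # composition shift
        pb, _ = _pb(y, ["case"] * 3 + ["control"] * 3)
        f = tmm_norm_factors(pb)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)
        assert f[0] != pytest.approx(1.0, abs=1e-3)  # shift detected


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_nan_propagates(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    def test_dominates_input_and_capped(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone in input ranks
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestNBLRT:
    def test_identical_columns_no_signal(self):
        col = np.arange(1, 41)
        y = np.tile(col[:, None], (1, 8))
        pb, design = _pb(y, ["case"] * 4 + ["control"] * 4)
        tab = fit_nb_lrt(pb, design, NBLRTSettings(dispersion=0.1))
        np.testing.assert_allclose(tab.logFC, 0.0, atol=1e-8)
        np.testing.assert_allclose(tab.LR, 0.0, atol=1e-8)
        # p = chi2.sf(LR, 1) ~ 1 - sqrt(2 LR / pi), so LR ~ 1e-12 gives p
        # within ~1e-6 of 1
        np.testing.assert_allclose(tab.p_value, 1.0, atol=1e-4)

    def test_poisson_limit_matches_glm_oracle(self):
        """With dispersion fixed at 0 the LRT must equal a Poisson GLM
        deviance difference computed independently by statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        G, S = 40, 12
        mu = rng.uniform(200, 2000, size=(G, 1)) * rng.uniform(0.8, 1.2, size=(1, S))
        y = rng.poisson(mu)
        pb, design = _pb(y, ["case"] * 6 + ["control"] * 6)
        tab = fit_nb_lrt(pb, design, NBLRTSettings(dispersion=0.0, use_tmm=False))
        x = np.array([1.0] * 6 + [0.0] * 6)
        off = np.log(y.sum(axis=0))
        for g in range(G):
            full = sm.GLM(
                y[g], sm.add_constant(x), family=sm.families.Poisson(), offset=off
            ).fit()
            null = sm.GLM(
                y[g], np.ones((S, 1)), family=sm.families.Poisson(), offset=off
            ).fit()
            assert tab.LR.iloc[g] == pytest.approx(
                null.deviance - full.deviance, abs=1e-4
            )
            assert tab.logFC.iloc[g] == pytest.approx(
                full.params[1] / np.log(2), abs=1e-5
            )

    def test_detects_large_effect(self):
        rng = np.random.default_rng(9)
        y = rng.poisson(100, size=(30, 12))
        y[0, :6] = rng.poisson(400, size=6)  # 4x in cases
        pb, design = _pb(y, ["case"] * 6 + ["control"] * 6)
        tab = fit_nb_lrt(pb, design)
        assert tab.adj_pval.iloc[0] < 0.01
        assert tab.logFC.iloc[0] == pytest.approx(2.0, abs=0.4)

    def test_requires_two_donors_per_group(self):
        y = np.ones((5, 3), dtype=int)
        pb, design = _pb(y, ["case", "control", "control"])
        with pytest.raises(ValueError, match="2 donors per condition"):
            fit_nb_lrt(pb, design)


class TestFilterExpressed:
    def test_all_zero_dropped_and_ubiquitous_kept(self):
        y = np.vstack([np.zeros(6), np.full(6, 500)]).astype(int)
        pb, _ = _pb(y, ["case"] * 3 + ["control"] * 3)
        mask = filter_expressed_pb(pb, min_cpm=1, min_samples=3)
        assert not mask[0] and mask[1]

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(12)
        y = rng.poisson(0.5, size=(200, 8)) * rng.poisson(300, size=(200, 8))
        pb, _ = _pb(y, ["case"] * 4 + ["control"] * 4)
        mask = filter_expressed_pb(pb, min_cpm=1, min_samples=4)
        lib = y.sum(axis=0)
        cpm = y / lib[None, :] * 1e6
        expected = (cpm > 1).sum(axis=1) >= 4
        np.testing.assert_array_equal(mask, expected)
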