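"""Single-cell QC, normalization, knockdown classification and the
downsampling-balanced Wilcoxon DE."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pimth17 import (
    DownsampleDEConfig,
    MarkerPanel,
    QCThresholds,
    SCSimConfig,
    call_de_genes,
    classify_pim_negative,
    downsample_balanced_de,
    generate_sc,
    joint_marker_state,
    log_normalize,
    qc_filter,
)
from pimth17.sc import rank_sum_pvalues
from statsmodels.stats.multitest import multipletests

from conftest import make_sc_experiment
from oracles import bh_stepup, ranksum_exact_p


def build_qc_experiment():
    """300 genes; cells engineered around the QC boundaries."""
    n_genes = 300
    rng = np.random.default_rng(0)
    gene_names = [f"MT-{i}" for i in range(10)] + [f"g{i}" for i in range(n_genes - 10)]

    def cell(n_detected, mito_fraction, total=1000):
        col = np.zeros(n_genes)
        mito = int(round(total * mito_fraction))
        col[0] = mito  # all mito counts on one gene
        non_mito_detected = n_detected - (1 if mito > 0 else 0)
        idx = rng.choice(np.arange(10, n_genes), size=non_mito_detected, replace=False)
        col[idx] = 1
        col[idx[0]] += total - mito - non_mito_detected
        return col

    cols = {
        "good": cell(250, 0.05),
        "mito_high": cell(250, 0.12),
        "mito_boundary": cell(250, 0.10),  # exactly 10% → kept (strict >)
        "genes_199": cell(199, 0.0),
        "genes_200": cell(200, 0.0),
        "zero_total": np.zeros(n_genes),
    }
    counts = np.column_stack(list(cols.values()))
    exp = make_sc_experiment(counts, gene_names)
    exp.barcodes = np.array(list(cols), dtype=object)
    return exp


class TestQCFilter:
    def test_boundary_cells_filtered_exactly(self):
        exp = build_qc_experiment()
        filtered, report = qc_filter(exp, QCThresholds())
        kept = set(filtered.barcodes)
        assert kept == {"good", "mito_boundary", "genes_200"}
        assert report.n_removed_mito == 1
        assert report.n_removed_low_genes == 1
        assert report.n_removed_zero_total == 1
        assert report.n_kept == 3
        assert filtered.n_genes == exp.n_genes  # gene universe unchanged

    def test_idempotent(self):
        exp = build_qc_experiment()
        once, _ = qc_filter(exp)
        twice, report2 = qc_filter(once)
        assert list(twice.barcodes) == list(once.barcodes)
        assert report2.n_kept == report2.n_input

    def test_all_passing_is_identity(self):
        counts = np.ones((300, 4))
        exp = make_sc_experiment(counts, [f"g{i}" for i in range(300)])
        filtered, report = qc_filter(exp)
        assert filtered.n_cells == 4
        assert report.n_removed_mito == report.n_removed_low_genes == 0


class TestLogNormalize:
    def test_formula(self):
        counts = np.zeros((3, 1))
        counts[0, 0] = 10
        counts[1, 0] = 9990
        exp = make_sc_experiment(counts, ["a", "b", "c"])
        x = log_normalize(exp, scale_factor=1e4).toarray()
        assert x[0, 0] == pytest.approx(np.log(1 + 10), rel=1e-12)
        assert x[2, 0] == 0.0

    def test_depth_invariance(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 20, size=50).astype(float)
        exp1 = make_sc_experiment(col[:, None], [f"g{i}" for i in range(50)])
        exp2 = make_sc_experiment(3 * col[:, None], [f"g{i}" for i in range(50)])
        assert np.allclose(
            log_normalize(exp1).toarray(), log_normalize(exp2).toarray()
        )

    def test_zero_total_cell_rejected(self):
        exp = make_sc_experiment(np.zeros((5, 2)), [f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="zero-total"):
            log_normalize(exp)


class TestClassification:
    def _exp(self):
        counts = np.array(
            # PIM1 PIM2 PIM3 TBX21 RORA  (rows) — 4 cells
            [[0, 1, 2, 0],
             [0, 0, 0, 0],
             [0, 0, 1, 0],
             [0, 1, 1, 2],
             [3, 0, 0, 0]],
            dtype=float,
        )
        return make_sc_experiment(
            counts, ["PIM1", "PIM2", "PIM3", "TBX21", "RORA"],
            sample_of=["TKD", "TKD", "Scr", "Scr"],
        )

    def test_pim_negative_requires_all_three_zero(self):
        exp = self._exp()
        neg, fractions = classify_pim_negative(exp)
        assert list(neg) == [True, False, False, True]
        assert fractions == {"TKD": 0.5, "Scr": 0.5}

    def test_missing_target_errors_by_name(self):
        exp = make_sc_experiment(np.ones((2, 2)), ["PIM1", "PIM2"])
        with pytest.raises(KeyError, match="PIM3"):
            classify_pim_negative(exp)

    def test_joint_marker_states(self):
        exp = self._exp()
        states = joint_marker_state(exp, MarkerPanel())
        assert states[0] == "PIM-/TBX21-/RORA+"
        assert states[1] == "PIM+/TBX21+/RORA-"
        assert states[3] == "PIM-/TBX21+/RORA-"

    def test_all_zero_cell_is_all_negative(self):
        counts = np.zeros((5, 1))
        exp = make_sc_experiment(counts, ["PIM1", "PIM2", "PIM3", "TBX21", "RORA"])
        assert joint_marker_state(exp)[0] == "PIM-/TBX21-/RORA-"

    def test_recovers_planted_silenced_fraction(self):
        cfg = SCSimConfig(n_genes=200, n_cells_scr=100, n_cells_tkd=3000,
                          silenced_fraction_tkd=0.53, seed=17)
        exp, _ = generate_sc(cfg)
        _, fractions = classify_pim_negative(exp)
        assert abs(fractions["TKD"] - 0.53) < 0.03


class TestRankSumAndBH:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + rng.uniform(-1, 1)
        p = rank_sum_pvalues(x[None, :], y[None, :])[0]
        assert p == pytest.approx(ranksum_exact_p(x, y), abs=1e-9)

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=8)
        y = rng.normal(0.5, 1, size=8)
        p_asym = rank_sum_pvalues(x[None, :], y[None, :], exact_max_n=0)[0]
        assert abs(p_asym - ranksum_exact_p(x, y)) < 0.01

    def test_bh_matches_handcomputed_stepup(self):
        p = [0.01, 0.02, 0.03, 0.04, 1.0]
        adj = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, [0.05, 0.05, 0.05, 0.05, 1.0])
        assert np.allclose(adj, bh_stepup(p))

    @pytest.mark.parametrize("seed", range(3))
    def test_bh_agrees_with_oracle_on_random_pvectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=25)
        assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_stepup(p))


class TestDownsampleDE:
    @staticmethod
    def _expr(seed=0, n_genes=60, n_cells=40, shift_first=0.0, n_case=20):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(5, size=(n_genes, n_cells)).astype(float)
        counts[0, :n_case] *= 2 ** shift_first
        exp = make_sc_experiment(np.round(counts), [f"g{i}" for i in range(n_genes)])
        return log_normalize(exp), pd.Index([f"g{i}" for i in range(n_genes)])

    def test_equal_sizes_degenerate_to_single_subset(self):
        expr, genes = self._expr()
        case = np.arange(20)
        ctrl = np.arange(20, 40)
        res = downsample_balanced_de(case, ctrl, expr,
                                     DownsampleDEConfig(n_subsets=10, seed=4),
                                     genes=genes)
        tested = res.table["ever_tested"]
        assert set(res.table.loc[tested, "signif_prop"].unique()) <= {0.0, 1.0}
        # all subsets identical
        assert np.allclose(res.log2fc.std(axis=1), 0.0)

    def test_seed_determinism_and_subset_order_invariance(self):
        expr, genes = self._expr(n_cells=60)
        case, ctrl = np.arange(15), np.arange(15, 60)
        cfg = DownsampleDEConfig(n_subsets=12, seed=9)
        r1 = downsample_balanced_de(case, ctrl, expr, cfg, genes=genes)
        r2 = downsample_balanced_de(case, ctrl, expr, cfg, genes=genes)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        # substream-per-subset: first subsets of a shorter run coincide
        r3 = downsample_balanced_de(case, ctrl, expr,
                                    DownsampleDEConfig(n_subsets=5, seed=9),
                                    genes=genes)
        assert np.allclose(r1.log2fc[:, :5], r3.log2fc, equal_nan=True)

    def test_symmetric_handling_when_case_is_larger(self):
        expr, genes = self._expr(n_cells=60)
        big, small = np.arange(40), np.arange(40, 60)
        res = downsample_balanced_de(big, small, expr,
                                     DownsampleDEConfig(n_subsets=5, seed=1),
                                     genes=genes)
        assert res.table["n_subsets_tested"].max() <= 5

    def test_planted_shift_reaches_full_signif_prop(self):
        expr, genes = self._expr(seed=3, n_genes=40, n_cells=300, shift_first=2.0, n_case=100)
        case, ctrl = np.arange(100), np.arange(100, 300)
        res = downsample_balanced_de(case, ctrl, expr,
                                     DownsampleDEConfig(n_subsets=20, seed=2),
                                     genes=genes)
        assert res.table.loc["g0", "signif_prop"] == 1.0
        assert res.table.loc["g0", "mean_log2fc"] > 0.24

    def test_too_small_case_group_rejected(self):
        expr, _ = self._expr()
        with pytest.raises(ValueError, match="at least 2"):
            downsample_balanced_de(np.array([0]), np.arange(1, 30), expr)

    def test_call_de_genes_monotone_in_threshold(self):
        expr, genes = self._expr(seed=5, n_genes=40, n_cells=200, shift_first=1.5, n_case=60)
        case, ctrl = np.arange(60), np.arange(60, 200)
        res = downsample_balanced_de(case, ctrl, expr,
                                     DownsampleDEConfig(n_subsets=10, seed=3),
                                     genes=genes)
        low = call_de_genes(res, 0.0).genes()
        mid = call_de_genes(res, 0.5).genes()
        high = call_de_genes(res, 1.0).genes()
        assert high <= mid <= low
        # threshold 0 admits every tested gene
        assert low == set(res.table.index[res.table["ever_tested"]].astype(str))
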