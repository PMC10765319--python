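"""Synthetic-data generator: determinism, null cases, planted-effect recovery
and marginal negative-binomial calibration."""

import numpy as np
import pytest

from pimth17 import (
    BulkSimConfig,
    SCSimConfig,
    generate_bulk,
    generate_sc,
)
from pimth17.containers import ConfigurationError

from oracles import nb_moment_dispersion


class TestBulkGenerator:
    def test_same_seed_reproduces_counts_exactly(self):
        a, _ = generate_bulk(BulkSimConfig(n_genes=100, seed=3))
        b, _ = generate_bulk(BulkSimConfig(n_genes=100, seed=3))
        assert a.counts.equals(b.counts)
        assert a.samples.equals(b.samples)

    def test_different_seed_changes_counts(self):
        a, _ = generate_bulk(BulkSimConfig(n_genes=100, seed=3))
        b, _ = generate_bulk(BulkSimConfig(n_genes=100, seed=4))
        assert not a.counts.equals(b.counts)

    def test_null_simulation_has_no_planted_genes(self):
        exp, truth = generate_bulk(BulkSimConfig(n_genes=100, de_fraction=0.0, seed=1))
        assert truth.de_genes == {}
        # conditions exchangeable: grand means agree within sampling noise
        scr = exp.counts.loc[:, exp.samples["condition"] == "Scr"].to_numpy().sum()
        tkd = exp.counts.loc[:, exp.samples["condition"] == "TKD"].to_numpy().sum()
        assert abs(np.log2(tkd / scr)) < 0.1

    def test_planted_fold_change_recovered_at_low_noise(self):
        """At vanishing dispersion and high depth, the TKD/Scr mean count
        ratio of each planted gene approaches 2^lfc."""
        cfg = BulkSimConfig(
            n_genes=100,
            de_fraction=0.2,
            lfc_magnitude=1.0,
            dispersion=1e-9,
            pair_sigma=0.0,
            lib_size_range=(10**9, 10**9),
            timepoints=("6h",),
            seed=5,
        )
        exp, truth = generate_bulk(cfg)
        scr = exp.counts.loc[:, exp.samples["condition"] == "Scr"].mean(axis=1)
        tkd = exp.counts.loc[:, exp.samples["condition"] == "TKD"].mean(axis=1)
        ratio = tkd / scr
        for gene, lfc in truth.de_genes.items():
            assert ratio[gene] == pytest.approx(2.0**lfc, rel=0.01)

    def test_truth_genes_within_universe(self):
        exp, truth = generate_bulk(BulkSimConfig(n_genes=50, de_fraction=0.2, seed=2))
        assert set(truth.de_genes) <= set(exp.genes)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"de_fraction": -0.1},
            {"de_fraction": 1.5},
            {"n_genes": 0},
            {"lib_size_range": (100, 10)},
            {"de_fraction": 0.001, "n_genes": 100},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            generate_bulk(BulkSimConfig(**kwargs))


class TestSCGenerator:
    def test_all_silenced_cells_have_zero_targets(self):
        cfg = SCSimConfig(
            n_genes=100, n_cells_scr=50, n_cells_tkd=100,
            silenced_fraction_tkd=1.0, seed=1,
        )
        exp, truth = generate_sc(cfg)
        tkd = exp.counts[:, exp.sample_of == "TKD"].toarray()
        for g in cfg.kd_target_genes:
            assert (tkd[exp.gene_index(g)] == 0).all()

    def test_silenced_fraction_concentrates_on_truth(self):
        cfg = SCSimConfig(n_genes=100, n_cells_scr=100, n_cells_tkd=3000,
                          silenced_fraction_tkd=0.53, seed=2)
        exp, truth = generate_sc(cfg)
        in_tkd = sum(1 for b in truth.silenced_cells if b.startswith("TKD"))
        assert abs(in_tkd / 3000 - 0.53) < 0.03

    def test_no_effect_genes_leaves_nontarget_genes_exchangeable(self):
        cfg = SCSimConfig(n_genes=200, n_cells_scr=1000, n_cells_tkd=1000,
                          effect_genes={}, dropout_shape=None, seed=3)
        exp, truth = generate_sc(cfg)
        sil = np.array([b in truth.silenced_cells for b in exp.barcodes])
        counts = exp.counts.toarray()
        kd_idx = [exp.gene_index(g) for g in cfg.kd_target_genes]
        other = np.setdiff1d(np.arange(exp.n_genes), kd_idx)
        m_sil = counts[np.ix_(other, np.flatnonzero(sil))].mean()
        m_not = counts[np.ix_(other, np.flatnonzero(~sil))].mean()
        assert abs(np.log2(m_sil / m_not)) < 0.05

    def test_determinism_and_mito_naming(self):
        cfg = SCSimConfig(n_genes=100, n_cells_scr=50, n_cells_tkd=50, seed=9)
        a, _ = generate_sc(cfg)
        b, _ = generate_sc(cfg)
        assert (a.counts != b.counts).nnz == 0
        assert a.features["is_mito"].sum() == round(0.05 * 100)
        assert a.features.loc[a.features["is_mito"], "gene_name"].str.startswith("MT-").all()

    def test_gene_universe_too_small_rejected(self):
        # the 3 knockdown targets alone exceed a 2-gene universe
        with pytest.raises(ConfigurationError):
            generate_sc(SCSimConfig(n_genes=2, n_cells_scr=5, n_cells_tkd=5, seed=0))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"silenced_fraction_tkd": 1.2},
            {"silenced_fraction_scr": -0.1},
            {"kd_target_genes": ("PIM1", "PIM2")},
            {"mean_depth": 0.0},
        ],
    )
    def test_invalid_sc_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            generate_sc(SCSimConfig(n_cells_scr=5, n_cells_tkd=5, **kwargs))

    def test_nb_dispersion_calibrated_by_moments(self):
        """Empirical per-gene dispersion matches the configured φ within 20%
        (method of moments over ≥1000 cells, dropout off)."""
        phi = 0.3
        cfg = SCSimConfig(n_genes=50, n_cells_scr=2000, n_cells_tkd=10,
                          silenced_fraction_scr=0.0, dispersion=phi,
                          dropout_shape=None, depth_sigma=0.0, seed=11)
        exp, _ = generate_sc(cfg)
        counts = exp.counts[:, exp.sample_of == "Scr"].toarray()
        means = counts.mean(axis=1, keepdims=True)
        # pool well-expressed genes for a stable moment estimate
        strong = means.ravel() > 5
        est = nb_moment_dispersion(counts[strong], np.broadcast_to(means[strong], counts[strong].shape))
        assert est == pytest.approx(phi, rel=0.2)
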