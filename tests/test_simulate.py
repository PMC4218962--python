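"""Generator contracts: shapes, determinism, and configured-law recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleopipe.simulate import (ConfigError, SimulationConfig,
                                simulate_mt_reads, simulate_panel,
                                simulate_reads, simulate_sex_counts,
                                simulate_truth, simulate_x_reads)


class TestPanel:
    def test_shape_domain_and_order(self):
        cfg = SimulationConfig(n_haplotypes=4, n_sites=10,
                               chrom_length=10_000, founder_count=2, seed=1)
        panel = simulate_panel(cfg)
        assert panel.haplotypes.shape == (4, 10)
        assert set(np.unique(panel.haplotypes)) <= {0, 1}
        assert np.all(np.diff(panel.positions) > 0)

    def test_minor_allele_count_every_site(self, small_panel):
        counts = small_panel.haplotypes.sum(axis=0)
        mac = np.minimum(counts, small_panel.n_haplotypes - counts)
        assert np.all(mac > 1)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_deterministic_under_seed(self, seed):
        cfg = SimulationConfig(n_haplotypes=8, n_sites=30,
                               chrom_length=50_000, founder_count=4,
                               seed=seed)
        a, b = simulate_panel(cfg), simulate_panel(cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.ref, b.ref)

    def test_sample_frequencies_track_drawn_frequencies(self):
        cfg = SimulationConfig(n_haplotypes=100, n_sites=5000, seed=3,
                               allele_freq_law=("uniform", 0.05, 0.95))
        panel = simulate_panel(cfg)
        dev = np.abs(panel.allele_frequencies() - panel.target_freqs)
        se = np.sqrt(panel.target_freqs * (1 - panel.target_freqs) / 100)
        # binomial mean absolute deviation is se * sqrt(2/pi)
        ratio = dev.mean() / (se * np.sqrt(2 / np.pi)).mean()
        assert 0.9 < ratio < 1.1

    def test_transition_fraction_controls_allele_pairs(self):
        cfg = SimulationConfig(n_haplotypes=20, n_sites=2000,
                               transition_fraction=1.0, seed=5)
        assert simulate_panel(cfg).is_transition_site().all()
        cfg0 = cfg.with_(transition_fraction=0.0)
        assert not simulate_panel(cfg0).is_transition_site().any()

    def test_rejects_invalid_configs(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_haplotypes=3).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(n_haplotypes=5).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(contamination_rate=1.5).validate()
        with pytest.raises(ConfigError):
            # MAC>1 unattainable at extreme frequencies
            simulate_panel(SimulationConfig(
                n_haplotypes=4, n_sites=20, chrom_length=10_000,
                founder_count=2, allele_freq_law=("constant", 1e-9), seed=0),
                max_redraws=5)


class TestTruth:
    def test_zero_switch_copies_one_panel_haplotype(self, small_panel,
                                                    small_config):
        truth = simulate_truth(small_panel,
                               small_config.with_(mosaic_switch_rate=0.0))
        for hap in (truth.hap_a, truth.hap_b):
            assert any(np.array_equal(hap, row)
                       for row in small_panel.haplotypes)
        assert truth.n_switches == (0, 0)

    def test_genotypes_are_haplotype_sums(self, small_panel, small_config):
        truth = simulate_truth(small_panel, small_config)
        assert np.array_equal(truth.genotypes, truth.hap_a + truth.hap_b)
        assert set(np.unique(truth.genotypes)) <= {0, 1, 2}

    def test_switch_counts_poisson(self):
        # rate 1e-6/bp over 10 Mb => ~10 expected switches per haplotype
        cfg = SimulationConfig(n_haplotypes=20, n_sites=2000,
                               chrom_length=10_000_000, founder_count=10,
                               mosaic_switch_rate=1e-6)
        panel = simulate_panel(cfg.with_(seed=0))
        span = panel.positions[-1] - panel.positions[0]
        lam = 1e-6 * span
        counts = []
        for seed in range(200):
            t = simulate_truth(panel, cfg.with_(seed=seed))
            counts.extend(t.n_switches)
        mean = np.mean(counts)
        se = np.sqrt(lam / len(counts))
        assert abs(mean - lam) < 3 * se


class TestReads:
    def test_mean_reads_per_site(self, small_panel, small_config):
        cfg = small_config.with_(n_sites=5000, chrom_length=5_000_000,
                                 coverage=2.0)
        panel = simulate_panel(cfg)
        truth = simulate_truth(panel, cfg)
        reads = simulate_reads(truth, panel, cfg)
        mean = len(reads) / panel.n_sites
        se = np.sqrt(2.0 / panel.n_sites)
        assert abs(mean - 2.0) < 3 * se

    def test_noise_free_limit_reproduces_truth_alleles(self, small_panel,
                                                       small_config):
        cfg = small_config.with_(deam_amp_5p=0.0, deam_amp_3p=0.0,
                                 contamination_rate=0.0, coverage=3.0,
                                 base_error_law=("constant", 1000))
        truth = simulate_truth(small_panel, cfg)
        reads = simulate_reads(truth, small_panel, cfg)
        pos_to_j = {p: j for j, p in enumerate(small_panel.positions)}
        for r in reads.itertuples():
            j = pos_to_j[r.pos]
            assert r.base in (small_panel.ref[j], small_panel.alt[j])
            dosage = truth.genotypes[j]
            if r.base == small_panel.alt[j]:
                assert dosage >= 1
            else:
                assert dosage <= 1

    def test_terminal_ct_rate_matches_amplitude(self):
        # homozygous-ref target over C/T-type sites: every terminal T on a
        # reference-C site is a deamination event
        cfg = SimulationConfig(n_haplotypes=20, n_sites=3000,
                               chrom_length=3_000_000, founder_count=4,
                               transition_fraction=1.0, deam_amp_5p=0.3,
                               deam_amp_3p=0.0, deam_decay=3.0,
                               contamination_rate=0.0, coverage=5.0,
                               base_error_law=("constant", 1000), seed=2)
        panel = simulate_panel(cfg)
        from paleopipe.simulate import DiploidTruth
        z = np.zeros(panel.n_sites, dtype=np.uint8)
        truth = DiploidTruth(hap_a=z, hap_b=z.copy(),
                             source_tracks=np.zeros((2, panel.n_sites),
                                                    dtype=np.int64))
        reads = simulate_reads(truth, panel, cfg)
        ref_c = pd.Series(panel.ref, index=panel.positions)
        at_c = reads[reads["pos"].map(ref_c) == "C"]
        term = at_c[at_c["dist5"] == 1]
        rate = (term["base"] == "T").mean()
        se = np.sqrt(0.3 * 0.7 / len(term))
        assert abs(rate - 0.3) < 3 * se

    def test_deterministic_under_seed(self, small_panel, small_config):
        truth = simulate_truth(small_panel, small_config)
        a = simulate_reads(truth, small_panel, small_config)
        b = simulate_reads(truth, small_panel, small_config)
        pd.testing.assert_frame_equal(a, b)


class TestMtAndSex:
    def test_no_contamination_means_no_contaminant_alleles(self):
        cfg = SimulationConfig(contamination_rate=0.0, deam_amp_5p=0.0,
                               deam_amp_3p=0.0,
                               base_error_law=("constant", 1000), seed=4)
        mt = simulate_mt_reads(cfg)
        contam = mt.reads["pos"].map(
            mt.diagnostics.set_index("pos")["contaminant"])
        assert (mt.reads["base"] != contam).all()

    def test_contaminant_read_fraction(self):
        cfg = SimulationConfig(contamination_rate=0.02, deam_amp_5p=0.0,
                               deam_amp_3p=0.0,
                               base_error_law=("constant", 1000), seed=6)
        mt = simulate_mt_reads(cfg, n_diagnostic=50, depth=100)
        contam = mt.reads["pos"].map(
            mt.diagnostics.set_index("pos")["contaminant"])
        frac = (mt.reads["base"] == contam).mean()
        se = np.sqrt(0.02 * 0.98 / len(mt.reads))
        assert abs(frac - 0.02) < 4 * se

    def test_xx_error_free_has_no_y_reads(self):
        cfg = SimulationConfig(seed=8)
        n_x, n_y = simulate_sex_counts("XX", cfg)
        assert n_y == 0 and n_x == 10_000
        with pytest.raises(ConfigError):
            simulate_sex_counts("XZ", cfg)

    def test_male_y_fraction(self):
        fracs = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed)
            n_x, n_y = simulate_sex_counts("XY", cfg)
            fracs.append(n_y / (n_x + n_y))
        assert abs(np.mean(fracs) - 0.089) < 0.005

    def test_x_reads_shapes_and_determinism(self):
        cfg = SimulationConfig(contamination_rate=0.05, seed=9)
        r1, s1 = simulate_x_reads(cfg, n_sites=300, depth=4)
        r2, s2 = simulate_x_reads(cfg, n_sites=300, depth=4)
        pd.testing.assert_frame_equal(r1, r2)
        assert set(r1["allele"].unique()) <= {0, 1}
        assert len(s1) == 300
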