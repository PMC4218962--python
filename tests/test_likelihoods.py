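"""Genotype-likelihood construction, masking rules and downsampling."""

import numpy as np
import pandas as pd
import pytest

from paleopipe.likelihoods import (FLAT, apply_deamination_mask,
                                   build_gl_matrix, downsample,
                                   site_genotype_likelihoods)
from paleopipe.simulate import (SimulationConfig, simulate_panel,
                                simulate_reads, simulate_truth)

from conftest import make_gl, make_panel


class TestSiteLikelihoods:
    def test_no_reads_gives_flat_uncovered(self):
        gl, uncovered = site_genotype_likelihoods(
            np.array([]), np.array([]), "A", "C")
        assert uncovered
        assert np.allclose(gl, FLAT)
        assert round(float(gl[0]), 4) == 0.3333

    def test_single_read_matches_closed_form(self):
        # one A at Q20 on an A/C site: e = 0.01
        gl, unc = site_genotype_likelihoods(
            np.array(["A"]), np.array([20.0]), "A", "C")
        raw = np.array([0.99, (0.99 + 0.01 / 3) / 2, 0.01 / 3])
        assert not unc
        np.testing.assert_allclose(gl, raw / raw.sum(), rtol=1e-12)

    def test_many_ref_reads_concentrate_on_hom_ref(self):
        gl, _ = site_genotype_likelihoods(
            np.array(["G"] * 10), np.full(10, 40.0), "G", "T")
        assert gl[0] > 0.999

    def test_off_allele_reads_discarded(self):
        gl, unc = site_genotype_likelihoods(
            np.array(["T", "T", "T"]), np.full(3, 30.0), "A", "C")
        assert unc and np.allclose(gl, FLAT)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            site_genotype_likelihoods(np.array(["A"]), np.array([-1.0]),
                                      "A", "C")
        with pytest.raises(ValueError):
            site_genotype_likelihoods(np.array(["A"]), np.array([30.0]),
                                      "A", "A")

    def test_triples_normalized_for_random_stacks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            bases = rng.choice(["A", "C", "G", "T"], n)
            quals = rng.uniform(2, 60, n)
            gl, _ = site_genotype_likelihoods(bases, quals, "A", "C")
            assert abs(gl.sum() - 1.0) < 1e-12


class TestDeaminationMask:
    def test_site_flat_resets_transition_site(self):
        panel = make_panel([[0], [1], [0], [1]], ref=["C"], alt=["T"])
        gl = make_gl([[0.001, 0.1, 0.899]], panel)
        out = apply_deamination_mask(gl, "site-flat")
        assert out.masked[0]
        np.testing.assert_allclose(out.gl[0], FLAT)
        assert round(float(out.gl[0, 1]), 4) == 0.3333

    def test_non_transition_site_unchanged(self):
        panel = make_panel([[0], [1], [0], [1]], ref=["A"], alt=["C"])
        gl = make_gl([[0.7, 0.2, 0.1]], panel)
        out = apply_deamination_mask(gl, "site-flat")
        assert not out.masked[0]
        np.testing.assert_allclose(out.gl[0], gl.gl[0])

    def test_genotype_flat_matches_hand_computation(self):
        # G/A site, reads all G: genotypes containing the damage product A
        # (G/A and A/A) are reset to 1/3 before renormalizing
        panel = make_panel([[0], [1], [0], [1]], ref=["G"], alt=["A"])
        triple = np.array([0.9, 0.09, 0.01])
        gl = make_gl([triple], panel)
        out = apply_deamination_mask(gl, "genotype-flat")
        expected = np.array([0.9, 1 / 3, 1 / 3])
        expected /= expected.sum()
        np.testing.assert_allclose(out.gl[0], expected, rtol=1e-12)

    @pytest.mark.parametrize("mode", ["site-flat", "genotype-flat"])
    def test_masking_idempotent(self, mode):
        panel = make_panel([[0, 0], [1, 1], [0, 1], [1, 0]],
                           ref=["C", "T"], alt=["T", "C"])
        gl = make_gl([[0.2, 0.5, 0.3], [0.6, 0.3, 0.1]], panel)
        once = apply_deamination_mask(gl, mode)
        twice = apply_deamination_mask(once, mode)
        np.testing.assert_allclose(once.gl, twice.gl)

    def test_unknown_mode_rejected(self):
        panel = make_panel([[0], [1], [0], [1]])
        gl = make_gl([[1, 1, 1]], panel)
        with pytest.raises(ValueError):
            apply_deamination_mask(gl, "strand-flat")


class TestBuildGLMatrix:
    def test_empty_reads_all_flat(self, small_panel):
        gl = build_gl_matrix(pd.DataFrame(columns=["pos", "base", "phred"]),
                             small_panel)
        assert gl.uncovered.all()
        flat_rows = np.tile(FLAT, (small_panel.n_sites, 1))
        np.testing.assert_allclose(gl.gl, flat_rows)

    def test_high_coverage_recovers_truth_at_unmasked_sites(self):
        cfg = SimulationConfig(n_haplotypes=20, n_sites=300,
                               chrom_length=600_000, founder_count=6,
                               coverage=30.0, deam_amp_5p=0.0,
                               deam_amp_3p=0.0, contamination_rate=0.0,
                               base_error_law=("constant", 1000), seed=13)
        panel = simulate_panel(cfg)
        truth = simulate_truth(panel, cfg)
        gl = build_gl_matrix(simulate_reads(truth, panel, cfg), panel)
        free = ~gl.masked & ~gl.uncovered
        assert free.sum() > 50
        assert np.array_equal(gl.gl[free].argmax(axis=1),
                              truth.genotypes[free])

    def test_all_transition_panel_fully_masked(self):
        cfg = SimulationConfig(n_haplotypes=8, n_sites=50,
                               chrom_length=100_000, founder_count=4,
                               transition_fraction=1.0, seed=14)
        panel = simulate_panel(cfg)
        truth = simulate_truth(panel, cfg)
        gl = build_gl_matrix(simulate_reads(truth, panel, cfg), panel)
        assert gl.masked.all()

    def test_read_outside_panel_rejected(self, small_panel):
        reads = pd.DataFrame({"pos": [999_999_999], "base": ["A"],
                              "phred": [30]})
        with pytest.raises(ValueError, match="absent from the panel"):
            build_gl_matrix(reads, small_panel)


class TestDownsample:
    def _reads(self, n=10_000):
        return pd.DataFrame({"pos": np.arange(n), "base": "A", "phred": 30})

    def test_full_fraction_is_identity(self):
        reads = self._reads(100)
        pd.testing.assert_frame_equal(downsample(reads, 1.0), reads)

    def test_half_fraction_binomial(self):
        kept = len(downsample(self._reads(), 0.5, seed=3))
        assert abs(kept - 5000) < 3 * np.sqrt(10_000 * 0.25)

    def test_deterministic(self):
        a = downsample(self._reads(), 0.3, seed=7)
        b = downsample(self._reads(), 0.3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, frac):
        with pytest.raises(ValueError):
            downsample(self._reads(10), frac)
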