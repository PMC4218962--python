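"""Copying-HMM posteriors: oracle equivalence, symmetries, limits."""

import numpy as np
import pytest

from paleopipe.impute import (GenotypePosterior, HMMParams,
                              _allele_pair_emission, brute_force_posterior,
                              call_genotypes, forward_backward)
from paleopipe.likelihoods import build_gl_matrix
from paleopipe.simulate import (SimulationConfig, simulate_panel,
                                simulate_reads, simulate_truth)

from conftest import make_gl, make_panel


def random_instance(rng, k_max=3, m_max=4):
    K = int(rng.integers(1, k_max + 1))
    M = int(rng.integers(1, m_max + 1))
    panel = make_panel(rng.integers(0, 2, (K, M)))
    gl = make_gl(rng.random((M, 3)) + 1e-3, panel)
    params = HMMParams(copy_error=float(rng.uniform(0.001, 0.2)),
                       switch_rate=float(rng.uniform(0.01, 0.5)))
    return gl, panel, params


class TestForwardBackward:
    def test_single_template_limit(self):
        panel = make_panel(np.zeros((1, 8)))
        gl = make_gl(np.ones((8, 3)), panel)
        post = forward_backward(gl, panel, HMMParams(copy_error=1e-9))
        assert np.all(post.gp[:, 0] > 1 - 1e-6)

    def test_matches_exhaustive_path_sum(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            gl, panel, params = random_instance(rng)
            fb = forward_backward(gl, panel, params)
            bf = brute_force_posterior(gl, panel, params)
            np.testing.assert_allclose(fb.gp, bf.gp, atol=1e-10)
            assert abs(fb.loglik - bf.loglik) < 1e-8

    def test_single_site_closed_form(self):
        # posterior at one site is proportional to sum_{j,k} gl * A
        rng = np.random.default_rng(1)
        H = np.array([[0], [1], [1]], dtype=np.uint8)
        panel = make_panel(H)
        glv = rng.random(3) + 0.1
        gl = make_gl([glv], panel)
        eps = 0.05
        A = _allele_pair_emission(eps)
        expected = np.zeros(3)
        for j in range(3):
            for k in range(3):
                expected += (glv / glv.sum()) * A[H[j, 0], H[k, 0]]
        expected /= expected.sum()
        post = forward_backward(gl, panel, HMMParams(copy_error=eps))
        np.testing.assert_allclose(post.gp[0], expected, atol=1e-12)

    def test_half_half_symmetry(self):
        # flat GLs, eps=0, panel {all-ref, all-alt}: het posterior is 1/2
        panel = make_panel(np.array([[0] * 5, [1] * 5]))
        gl = make_gl(np.ones((5, 3)), panel)
        post = forward_backward(gl, panel,
                                HMMParams(copy_error=0.0, switch_rate=0.1))
        np.testing.assert_allclose(post.gp[:, 1], 0.5, atol=1e-12)

    def test_perfect_copy_limit_recovers_truth(self):
        cfg = SimulationConfig(n_haplotypes=20, n_sites=400,
                               chrom_length=800_000, founder_count=6,
                               coverage=30.0, deam_amp_5p=0.0,
                               deam_amp_3p=0.0, contamination_rate=0.0,
                               base_error_law=("constant", 1000), seed=21)
        panel = simulate_panel(cfg)
        truth = simulate_truth(panel, cfg)
        gl = build_gl_matrix(simulate_reads(truth, panel, cfg), panel)
        post = forward_backward(gl, panel)
        calls = call_genotypes(post, 0.99)
        called = calls.called_mask
        assert called.mean() > 0.9
        assert np.array_equal(calls.genotypes[called],
                              truth.genotypes[called])
        # every called genotype matches; argmax matches truth genome-wide
        assert (post.gp.argmax(axis=1) == truth.genotypes).mean() > 0.99

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        gl, panel, params = random_instance(rng, k_max=3, m_max=4)
        post = forward_backward(gl, panel, params)
        np.testing.assert_allclose(post.gp.sum(axis=1), 1.0, atol=1e-10)

    def test_haplotype_label_symmetry(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, (5, 12))
        panel = make_panel(H)
        gl = make_gl(rng.random((12, 3)) + 0.05, panel)
        post = forward_backward(gl, panel)
        perm = rng.permutation(5)
        panel_p = make_panel(H[perm])
        post_p = forward_backward(gl, panel_p)
        np.testing.assert_allclose(post.gp, post_p.gp, atol=1e-12)
        assert abs(post.loglik - post_p.loglik) < 1e-10

    def test_masked_site_imputed_from_flanks(self):
        # flat-GL site planted inside a perfectly copied tract recovers the
        # panel allele with high confidence from >= 50 informative flanks
        rng = np.random.default_rng(9)
        K, M = 6, 121
        H = rng.integers(0, 2, (K, M)).astype(np.uint8)
        panel = make_panel(H)
        truth_g = H[0] + H[1]
        sharp = np.full((M, 3), 1e-6)
        sharp[np.arange(M), truth_g] = 1.0
        mid = M // 2
        sharp[mid] = 1.0
        gl = make_gl(sharp, panel)
        post = forward_backward(gl, panel, HMMParams(copy_error=0.001))
        assert post.gp[mid, truth_g[mid]] >= 0.99

    def test_site_mismatch_rejected(self):
        panel = make_panel(np.zeros((2, 4)))
        gl = make_gl(np.ones((3, 3)), panel)
        with pytest.raises(ValueError):
            forward_backward(gl, panel)


class TestCallGenotypes:
    def _post(self, gp):
        gp = np.asarray(gp, dtype=float)
        return GenotypePosterior(positions=np.arange(len(gp)), gp=gp,
                                 loglik=0.0)

    def test_threshold_pass_and_fail(self):
        post = self._post([[0.995, 0.004, 0.001], [0.5, 0.3, 0.2]])
        calls99 = call_genotypes(post, 0.99)
        assert calls99.genotypes[0] == 0 and calls99.genotypes[1] == -1
        calls85 = call_genotypes(post, 0.85)
        assert calls85.genotypes[1] == -1

    def test_ties_are_missing(self):
        post = self._post([[0.5, 0.5, 0.0]])
        assert call_genotypes(post, 0.4).genotypes[0] == -1

    def test_lower_threshold_never_reduces_calls(self):
        rng = np.random.default_rng(5)
        gp = rng.dirichlet([1, 1, 1], size=200)
        post = self._post(gp)
        n99 = call_genotypes(post, 0.99).called_mask.sum()
        n85 = call_genotypes(post, 0.85).called_mask.sum()
        assert n85 >= n99

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_genotypes(self._post([[1, 0, 0]]), 0.2)


class TestBruteForce:
    def test_instance_size_guard(self):
        panel = make_panel(np.zeros((4, 10)))
        gl = make_gl(np.ones((10, 3)), panel)
        with pytest.raises(ValueError, match="too large"):
            brute_force_posterior(gl, panel)
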