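import numpy as np
import pytest

from paleopipe.likelihoods import GLMatrix
from paleopipe.simulate import ReferencePanel, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_haplotypes=20, n_sites=200,
                            chrom_length=400_000, founder_count=6, seed=11)


@pytest.fixture
def small_panel(small_config):
    from paleopipe.simulate import simulate_panel
    return simulate_panel(small_config)


def make_panel(haplotypes, positions=None, ref=None, alt=None,
               chrom="1") -> ReferencePanel:
    """Hand-built panel for constructed HMM/GL instances."""
    H = np.asarray(haplotypes, dtype=np.uint8)
    K, M = H.shape
    if positions is None:
        positions = np.arange(1, M + 1) * 1000
    if ref is None:
        ref = np.array(["A"] * M)
    if alt is None:
        alt = np.array(["C"] * M)
    return ReferencePanel(chrom=chrom, positions=np.asarray(positions),
                          ref=np.asarray(ref), alt=np.asarray(alt),
                          haplotypes=H)


def make_gl(gl_rows, panel) -> GLMatrix:
    """GLMatrix wrapper around a raw (M, 3) likelihood array."""
    gl = np.asarray(gl_rows, dtype=float)
    gl = gl / gl.sum(axis=1, keepdims=True)
    M = gl.shape[0]
    return GLMatrix(chrom=panel.chrom, positions=panel.positions[:M],
                    ref=panel.ref[:M], alt=panel.alt[:M], gl=gl,
                    uncovered=np.zeros(M, bool), masked=np.zeros(M, bool))
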