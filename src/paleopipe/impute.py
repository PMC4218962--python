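"""Diploid haplotype-copying (Li-Stephens) imputation HMM.

The target diploid genome is modeled as an ordered pair of imperfect
mosaics of the K phased panel haplotypes.  The hidden state at site m is
the pair (j, k) of copied haplotypes; each haplotype independently either
stays (probability exp(-rho)) or jumps to a uniformly chosen haplotype.
Copying is imperfect: the target allele differs from the copied panel
allele with miscopy probability epsilon.  The emission at a site sums the
genotype likelihoods against the allele-pair distribution implied by the
state, so low-coverage and masked (flat-likelihood) sites are imputed from
flanking haplotype context.

The forward-backward pass is O(M K^2) using the rank-1 structure of the
jump-uniform transition; per-site rescaling keeps M=10^4, K=100 runs free
of underflow.  ``brute_force_posterior`` enumerates all state paths and is
exported for the test suite only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .likelihoods import GLMatrix
from .simulate import ReferencePanel


@dataclass(frozen=True)
class HMMParams:
    """Copying-model parameters.

    copy_error : per-site miscopy probability epsilon, in [0, 0.5).
    switch_rate : per-site recombination parameter rho (expected switches
        per haplotype per site); with the default 1e-3 a 10^4-site
        chromosome sees ~10 switches per haplotype.
    """

    copy_error: float = 0.001
    switch_rate: float = 1e-3
    use_map: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.copy_error < 0.5:
            raise ValueError("copy_error must be in [0, 0.5)")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")


@dataclass
class GenotypePosterior:
    """Per-site posterior genotype probabilities (GP) and data log-likelihood."""

    positions: np.ndarray
    gp: np.ndarray  # (M, 3), rows sum to 1
    loglik: float

    @property
    def n_sites(self) -> int:
        return self.gp.shape[0]


@dataclass
class CalledGenotypes:
    """Thresholded genotype calls; -1 encodes a missing call."""

    positions: np.ndarray
    genotypes: np.ndarray  # int8 dosages {0,1,2}, -1 missing
    threshold: float

    @property
    def called_mask(self) -> np.ndarray:
        return self.genotypes >= 0

    @property
    def call_rate(self) -> float:
        return float(self.called_mask.mean())


def _allele_pair_emission(eps: float) -> np.ndarray:
    """A[a, b, g]: P(genotype g | copied alleles a, b) under miscopy eps.

    Each of the two target alleles is an independent miscopy-eps draw from
    its copied panel allele; g is the alt dosage.
    """
    A = np.empty((2, 2, 3))
    for a in (0, 1):
        for b in (0, 1):
            pa = 1.0 - eps if a == 1 else eps
            pb = 1.0 - eps if b == 1 else eps
            A[a, b] = [(1 - pa) * (1 - pb),
                       pa * (1 - pb) + (1 - pa) * pb,
                       pa * pb]
    return A


def _pair_transition(V: np.ndarray, q: float, c: float) -> np.ndarray:
    """Apply the factorized pair transition T V T, T = q I + c J."""
    cs = V.sum(axis=0)
    TV = q * V + c * cs[None, :]
    rs = TV.sum(axis=1)
    return q * TV + c * rs[:, None]


def forward_backward(gl: GLMatrix, panel: ReferencePanel,
                     params: HMMParams = HMMParams()) -> GenotypePosterior:
    """Posterior genotype probabilities from the diploid copying HMM.

    Sites of ``gl`` and ``panel`` must coincide in order.  The per-site
    posterior combines the state posterior (with the site's own emission
    divided out) with the site's genotype likelihoods and the state's
    allele-pair distribution, then normalizes.
    """
    params.validate()
    if panel.n_haplotypes == 0 or panel.n_sites == 0:
        raise ValueError("empty panel")
    if gl.n_sites != panel.n_sites or not np.array_equal(
            gl.positions, panel.positions):
        raise ValueError("GL sites do not match panel sites")

    H = panel.haplotypes
    K, M = H.shape
    glm = gl.gl
    A = _allele_pair_emission(params.copy_error)
    # per-site 2x2 emission over copied allele pairs
    e2 = np.einsum("mg,abg->mab", glm, A)

    q = float(np.exp(-params.switch_rate))
    c = (1.0 - q) / K
    hf = H.astype(float)

    def emission(m: int) -> np.ndarray:
        # rank-1 expansion of the 2x2 table over haplotype alleles
        h = hf[:, m]
        e00, e01 = e2[m, 0, 0], e2[m, 0, 1]
        e10, e11 = e2[m, 1, 0], e2[m, 1, 1]
        return (e00 + (e10 - e00) * h[:, None] + (e01 - e00) * h[None, :]
                + (e11 - e10 - e01 + e00) * (h[:, None] * h[None, :]))

    # forward pass stores per-site scales plus block checkpoints; the
    # backward pass re-runs the forward within each block, keeping the
    # working set small instead of holding all M K^2 forward matrices
    block = 64
    n_blocks = (M + block - 1) // block
    checkpoints = np.empty((n_blocks, K, K))
    scales = np.empty(M)
    a = emission(0) / (K * K)
    scales[0] = a.sum()
    a = a / scales[0]
    checkpoints[0] = a
    for m in range(1, M):
        a = _pair_transition(a, q, c) * emission(m)
        scales[m] = a.sum()
        a = a / scales[m]
        if m % block == 0:
            checkpoints[m // block] = a
    loglik = float(np.log(scales).sum())

    gp = np.empty((M, 3))
    beta = np.ones((K, K))
    buf = np.empty((block, K, K))
    for b in range(n_blocks - 1, -1, -1):
        m0 = b * block
        m1 = min(m0 + block, M)
        a = checkpoints[b]
        buf[0] = a
        for i, m in enumerate(range(m0 + 1, m1), start=1):
            a = _pair_transition(a, q, c) * emission(m) / scales[m]
            buf[i] = a
        for m in range(m1 - 1, m0 - 1, -1):
            E = emission(m)
            gamma = buf[m - m0] * beta       # state posterior, sums to 1
            W = np.where(E > 0, gamma / E, 0.0)  # own emission divided out
            h1 = hf[:, m]
            B = np.vstack([1.0 - h1, h1])  # (2, K) allele-class indicators
            S = B @ W @ B.T                # class-aggregated state posterior
            trip = glm[m] * np.einsum("ab,abg->g", S, A)
            gp[m] = trip / trip.sum()
            if m > 0:
                beta = _pair_transition(beta * E, q, c) / scales[m]

    return GenotypePosterior(positions=gl.positions.copy(), gp=gp,
                             loglik=loglik)


def call_genotypes(post: GenotypePosterior,
                   threshold: float = 0.99) -> CalledGenotypes:
    """Argmax genotype where max GP >= threshold; ties and low GP -> missing."""
    if not (1 / 3 < threshold <= 1.0):
        raise ValueError("threshold must be in (1/3, 1]")
    gp = post.gp
    best = gp.max(axis=1)
    calls = gp.argmax(axis=1).astype(np.int8)
    tied = (gp == best[:, None]).sum(axis=1) > 1
    calls[(best < threshold) | tied] = -1
    return CalledGenotypes(positions=post.positions.copy(),
                           genotypes=calls, threshold=threshold)


def brute_force_posterior(gl: GLMatrix, panel: ReferencePanel,
                          params: HMMParams = HMMParams(),
                          max_paths: int = 10 ** 6) -> GenotypePosterior:
    """Exact path-sum posterior by exhaustive enumeration (test oracle).

    Enumerates all (K^2)^M hidden-state paths; refuses instances beyond
    ``max_paths``.
    """
    params.validate()
    H = panel.haplotypes
    K, M = H.shape
    n_paths = (K * K) ** M
    if n_paths > max_paths:
        raise ValueError(f"instance too large: {n_paths} paths")
    glm = gl.gl
    A = _allele_pair_emission(params.copy_error)
    q = float(np.exp(-params.switch_rate))
    c = (1.0 - q) / K

    def hap_trans(i: int, j: int) -> float:
        return q + c if i == j else c

    states = list(itertools.product(range(K), repeat=2))
    joint = np.zeros((M, 3))
    total = 0.0
    for path in itertools.product(states, repeat=M):
        p = 1.0 / (K * K)
        for m in range(1, M):
            p *= hap_trans(path[m - 1][0], path[m][0])
            p *= hap_trans(path[m - 1][1], path[m][1])
        ems = np.array([
            glm[m] * A[H[path[m][0], m], H[path[m][1], m]]
            for m in range(M)
        ])  # (M, 3) per-genotype emission terms
        site_sums = ems.sum(axis=1)
        full = p * site_sums.prod()
        total += full
        for m in range(M):
            rest = site_sums.prod() / site_sums[m] if site_sums[m] > 0 else 0.0
            joint[m] += p * rest * ems[m]
    gp = joint / joint.sum(axis=1, keepdims=True)
    return GenotypePosterior(positions=gl.positions.copy(), gp=gp,
                             loglik=float(np.log(total)))
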