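"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure a low-coverage ancient-DNA
analysis assumes: a phased biallelic reference panel (minor allele count
strictly greater than 1 at every site), a diploid target genome built as a
recombination mosaic of panel haplotypes, Poisson-coverage shotgun reads
carrying Phred-scale base errors, terminal cytosine deamination (5' C->T,
3' G->A, exponentially decaying from the read ends), a modern-like
contaminant read fraction, mtDNA read stacks with diagnostic positions, and
X/Y read counts by genetic sex.

All randomness flows through :class:`numpy.random.Generator` seeded from the
config, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

BASES = np.array(["A", "C", "G", "T"])
BASE_CODE = {b: i for i, b in enumerate(BASES)}
TRANSITION_PAIRS = [("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")]
TRANSVERSION_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
]

READ_COLUMNS = ["chrom", "pos", "base", "phred", "strand", "dist5", "dist3"]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Distribution laws are tuples: ``("constant", v)``, ``("uniform", lo, hi)``,
    ``("normal", mu, sd)`` or ``("truncnorm", mu, sd, lo, hi)``.

    Attributes
    ----------
    n_haplotypes : panel size K (phased haplotypes; must be even, >= 4).
    n_sites : number of biallelic panel sites M.
    chrom_length : chromosome length in bp over which sites are placed.
    founder_count : number of panel haplotypes the target mosaics from.
    allele_freq_law : per-site derived-allele-frequency distribution.
    mosaic_switch_rate : per-bp founder-switch probability of the target.
    coverage : mean reads per site (x).
    base_error_law : Phred base-quality distribution.
    deam_amp_5p : C->T probability at the 5'-terminal read position.
    deam_amp_3p : G->A probability at the 3'-terminal read position.
    deam_decay : exponential decay length (read positions) of deamination.
    fragment_length_law : read/fragment length distribution (bp).
    contamination_rate : fraction of reads from a modern-like contaminant.
    transition_fraction : fraction of panel sites with C/T or G/A alleles.
    """

    n_haplotypes: int = 100
    n_sites: int = 5000
    chrom_length: int = 5_000_000
    founder_count: int = 10
    allele_freq_law: tuple = ("uniform", 0.05, 0.95)
    mosaic_switch_rate: float = 1e-6
    coverage: float = 1.0
    base_error_law: tuple = ("constant", 30)
    deam_amp_5p: float = 0.2
    deam_amp_3p: float = 0.2
    deam_decay: float = 3.0
    fragment_length_law: tuple = ("truncnorm", 60.0, 15.0, 30, 150)
    contamination_rate: float = 0.01
    transition_fraction: float = 0.66
    chrom: str = "1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ConfigError(
                "n_haplotypes must be even and >= 4 for a MAC>1 panel"
            )
        if self.n_sites < 2:
            raise ConfigError("n_sites must be >= 2")
        if self.n_sites > self.chrom_length:
            raise ConfigError("more sites than base pairs")
        if self.founder_count < 1 or self.founder_count > self.n_haplotypes:
            raise ConfigError("founder_count must be in [1, n_haplotypes]")
        for name in ("deam_amp_5p", "deam_amp_3p", "contamination_rate",
                     "transition_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.coverage < 0:
            raise ConfigError("coverage must be >= 0")
        if self.deam_decay <= 0:
            raise ConfigError("deam_decay must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def draw_law(law: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` samples from a distribution-law tuple."""
    kind = law[0]
    if kind == "constant":
        return np.full(size, law[1], dtype=float)
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "normal":
        return rng.normal(law[1], law[2], size)
    if kind == "truncnorm":
        mu, sd, lo, hi = law[1:5]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size,
                                   random_state=rng)
    raise ConfigError(f"unknown distribution law {law!r}")


@dataclass
class ReferencePanel:
    """Phased biallelic haplotype matrix with positions and alleles.

    ``haplotypes`` is a (K, M) uint8 array of 0 (ref) / 1 (alt);
    ``positions`` are 1-based and strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray  # base characters, shape (M,)
    alt: np.ndarray
    haplotypes: np.ndarray  # (K, M)
    target_freqs: np.ndarray | None = None  # frequency each site was drawn at

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Sample alternate-allele frequency at each site."""
        return self.haplotypes.mean(axis=0)

    def is_transition_site(self) -> np.ndarray:
        """True where the ref/alt pair is C/T or G/A (deamination-prone)."""
        pairs = np.char.add(self.ref.astype(str), self.alt.astype(str))
        return np.isin(pairs, ["CT", "TC", "GA", "AG"])


@dataclass
class DiploidTruth:
    """Known diploid target genome used as ground truth.

    genotypes = hap_a + hap_b elementwise (alt-allele dosage in {0,1,2}).
    ``source_tracks`` records the mosaicked panel-haplotype index per site
    for each of the two haplotypes; ``n_switches`` the realized founder-switch
    event counts.
    """

    hap_a: np.ndarray
    hap_b: np.ndarray
    source_tracks: np.ndarray  # (2, M) panel haplotype index
    n_switches: tuple[int, int] = (0, 0)

    @property
    def genotypes(self) -> np.ndarray:
        return (self.hap_a + self.hap_b).astype(np.int8)


@dataclass
class MtReadSet:
    """mtDNA read observations plus the diagnostic-position table.

    ``diagnostics`` has columns pos, endogenous, contaminant (base chars).
    """

    reads: pd.DataFrame
    diagnostics: pd.DataFrame


def simulate_panel(config: SimulationConfig,
                   max_redraws: int = 1000) -> ReferencePanel:
    """Simulate a phased reference panel with MAC > 1 at every site.

    Per site a derived-allele frequency is drawn from ``allele_freq_law``
    and K haplotype alleles are drawn Bernoulli at that frequency; site
    columns violating minor-allele-count > 1 are redrawn (bounded by
    ``max_redraws`` rounds, after which a ConfigError is raised).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, M = config.n_haplotypes, config.n_sites

    positions = np.sort(
        rng.choice(config.chrom_length, size=M, replace=False)
    ).astype(np.int64) + 1

    freqs = np.clip(draw_law(config.allele_freq_law, M, rng), 0.0, 1.0)
    haps = (rng.random((K, M)) < freqs).astype(np.uint8)
    for _ in range(max_redraws):
        mac = np.minimum(haps.sum(axis=0), K - haps.sum(axis=0))
        bad = np.flatnonzero(mac <= 1)
        if bad.size == 0:
            break
        haps[:, bad] = (rng.random((K, bad.size)) < freqs[bad]).astype(np.uint8)
    else:
        raise ConfigError(
            "could not satisfy minor allele count > 1; "
            "frequency law too extreme for this panel size"
        )

    is_ts = rng.random(M) < config.transition_fraction
    ref = np.empty(M, dtype="<U1")
    alt = np.empty(M, dtype="<U1")
    ts_pick = rng.integers(len(TRANSITION_PAIRS), size=M)
    tv_pick = rng.integers(len(TRANSVERSION_PAIRS), size=M)
    for i in range(M):
        r, a = (TRANSITION_PAIRS[ts_pick[i]] if is_ts[i]
                else TRANSVERSION_PAIRS[tv_pick[i]])
        ref[i], alt[i] = r, a

    return ReferencePanel(chrom=config.chrom, positions=positions,
                          ref=ref, alt=alt, haplotypes=haps,
                          target_freqs=freqs)


def simulate_truth(panel: ReferencePanel,
                   config: SimulationConfig) -> DiploidTruth:
    """Build a diploid target as a recombination mosaic of panel haplotypes.

    ``founder_count`` haplotypes are sampled from the panel; each target
    haplotype copies from a founder, switching founders along the chromosome
    as a Poisson process with per-bp rate ``mosaic_switch_rate``.
    """
    config.validate()
    if panel.n_sites == 0:
        raise ConfigError("empty panel")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    M = panel.n_sites
    founders = rng.choice(panel.n_haplotypes, size=config.founder_count,
                          replace=False)
    gaps = np.diff(panel.positions).astype(float)

    tracks = np.empty((2, M), dtype=np.int64)
    switch_counts = []
    for h in range(2):
        current = founders[rng.integers(config.founder_count)]
        n_events = rng.poisson(config.mosaic_switch_rate * gaps)
        tracks[h, 0] = current
        total = 0
        for i, k in enumerate(n_events):
            if k > 0:
                current = founders[rng.integers(config.founder_count)]
                total += int(k)
            tracks[h, i + 1] = current
        switch_counts.append(total)

    hap_a = panel.haplotypes[tracks[0], np.arange(M)].astype(np.uint8)
    hap_b = panel.haplotypes[tracks[1], np.arange(M)].astype(np.uint8)
    return DiploidTruth(hap_a=hap_a, hap_b=hap_b, source_tracks=tracks,
                        n_switches=(switch_counts[0], switch_counts[1]))


def _apply_deamination(base_codes, site_ref_code, site_alt_code, site_idx,
                       dist5, dist3, config, rng):
    """In-place C->T (5') and G->A (3') conversion with exponential decay."""
    lam = config.deam_decay
    # C->T driven by distance from the 5' read end
    p5 = config.deam_amp_5p * np.exp(-(dist5 - 1) / lam)
    is_c = base_codes == BASE_CODE["C"]
    flip = is_c & (rng.random(base_codes.size) < p5)
    base_codes[flip] = BASE_CODE["T"]
    # G->A driven by distance from the 3' read end
    p3 = config.deam_amp_3p * np.exp(-(dist3 - 1) / lam)
    is_g = base_codes == BASE_CODE["G"]
    flip = is_g & (rng.random(base_codes.size) < p3)
    base_codes[flip] = BASE_CODE["A"]
    return base_codes


def simulate_reads(truth: DiploidTruth, panel: ReferencePanel,
                   config: SimulationConfig) -> pd.DataFrame:
    """Simulate per-site shotgun read observations at panel sites.

    Per site the read count is Poisson(coverage).  Each read copies a
    uniformly chosen truth haplotype, or with probability
    ``contamination_rate`` carries a contaminant allele drawn from the panel
    allele frequency.  Deamination is applied to the molecule (C->T decaying
    from the 5' end, G->A from the 3' end), then a Phred-scale sequencing
    error substitutes a uniform other base.

    Returns a DataFrame with columns chrom, pos, base, phred, strand,
    dist5, dist3 plus the hidden ``is_contaminant`` flag.
    """
    config.validate()
    if config.coverage <= 0:
        raise ConfigError("coverage must be > 0 to simulate reads")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    M = panel.n_sites
    counts = rng.poisson(config.coverage, M)
    site_idx = np.repeat(np.arange(M), counts)
    n = site_idx.size

    freqs = panel.allele_frequencies()
    is_contam = rng.random(n) < config.contamination_rate
    hap_pick = rng.integers(2, size=n)
    truth_alleles = np.where(hap_pick == 0, truth.hap_a[site_idx],
                             truth.hap_b[site_idx])
    contam_alleles = (rng.random(n) < freqs[site_idx]).astype(np.uint8)
    alleles = np.where(is_contam, contam_alleles, truth_alleles)

    ref_code = np.array([BASE_CODE[b] for b in panel.ref])
    alt_code = np.array([BASE_CODE[b] for b in panel.alt])
    base_codes = np.where(alleles == 1, alt_code[site_idx],
                          ref_code[site_idx]).astype(np.int64)

    frag_len = np.maximum(
        np.rint(draw_law(config.fragment_length_law, n, rng)), 1
    ).astype(np.int64)
    dist5 = rng.integers(1, frag_len + 1)
    dist3 = frag_len - dist5 + 1
    strand = np.where(rng.random(n) < 0.5, "+", "-")

    base_codes = _apply_deamination(base_codes, ref_code, alt_code, site_idx,
                                    dist5, dist3, config, rng)

    phred = np.maximum(np.rint(draw_law(config.base_error_law, n, rng)),
                       2).astype(np.int64)
    e = 10.0 ** (-phred / 10.0)
    err = rng.random(n) < e
    base_codes[err] = (base_codes[err] + rng.integers(1, 4, err.sum())) % 4

    return pd.DataFrame({
        "chrom": panel.chrom,
        "pos": panel.positions[site_idx],
        "base": BASES[base_codes],
        "phred": phred,
        "strand": strand,
        "dist5": dist5,
        "dist3": dist3,
        "is_contaminant": is_contam,
    })


def simulate_invariant_reads(config: SimulationConfig, n_sites: int = 2000,
                             ) -> tuple[pd.DataFrame, dict[int, str]]:
    """Reads over invariant C/G reference positions for damage profiling.

    Damage profiles are counted against positions where the genome matches
    the reference (the overwhelming majority in real data), so every
    observed C->T / G->A is a candidate deamination event rather than a
    genuine alternate allele.  Returns the read table and the
    position -> reference-base map.
    """
    config.validate()
    inv_cfg = config.with_(n_sites=n_sites, transition_fraction=1.0,
                           contamination_rate=0.0,
                           seed=int(np.random.SeedSequence(
                               [config.seed, 6]).generate_state(1)[0]
                               % (2 ** 31)))
    panel = simulate_panel(inv_cfg)
    z = np.zeros(panel.n_sites, dtype=np.uint8)
    truth = DiploidTruth(hap_a=z, hap_b=z.copy(),
                         source_tracks=np.zeros((2, panel.n_sites),
                                                dtype=np.int64))
    reads = simulate_reads(truth, panel, inv_cfg)
    site_alleles = dict(zip(panel.positions.tolist(), panel.ref.tolist()))
    return reads, site_alleles


def simulate_mt_reads(config: SimulationConfig, n_diagnostic: int = 50,
                      depth: float = 100.0, mt_length: int = 16569,
                      transversions_only: bool = True) -> MtReadSet:
    """Simulate mtDNA reads at diagnostic positions.

    The endogenous consensus differs from a contaminant haplotype at
    ``n_diagnostic`` positions; a fraction ``contamination_rate`` of reads
    at each position comes from the contaminant.  Diagnostic substitutions
    default to transversions, the damage-robust choice practitioners make
    when estimating contamination from mtDNA; set ``transversions_only``
    False to include transition (C/T, G/A) diagnostics.  Deamination and
    Phred errors are applied exactly as for nuclear reads.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    positions = np.sort(rng.choice(mt_length, size=n_diagnostic,
                                   replace=False)) + 1
    pairs = TRANSVERSION_PAIRS if transversions_only else (
        TRANSVERSION_PAIRS + 2 * TRANSITION_PAIRS)
    pick = rng.integers(len(pairs), size=n_diagnostic)
    endog = np.array([pairs[i][0] for i in pick])
    contam = np.array([pairs[i][1] for i in pick])

    counts = rng.poisson(depth, n_diagnostic)
    site_idx = np.repeat(np.arange(n_diagnostic), counts)
    n = site_idx.size
    is_contam = rng.random(n) < config.contamination_rate
    endog_code = np.array([BASE_CODE[b] for b in endog])
    contam_code = np.array([BASE_CODE[b] for b in contam])
    base_codes = np.where(is_contam, contam_code[site_idx],
                          endog_code[site_idx]).astype(np.int64)

    frag_len = np.maximum(
        np.rint(draw_law(config.fragment_length_law, n, rng)), 1
    ).astype(np.int64)
    dist5 = rng.integers(1, frag_len + 1)
    dist3 = frag_len - dist5 + 1
    base_codes = _apply_deamination(base_codes, endog_code, contam_code,
                                    site_idx, dist5, dist3, config, rng)
    phred = np.maximum(np.rint(draw_law(config.base_error_law, n, rng)),
                       2).astype(np.int64)
    e = 10.0 ** (-phred / 10.0)
    err = rng.random(n) < e
    base_codes[err] = (base_codes[err] + rng.integers(1, 4, err.sum())) % 4

    reads = pd.DataFrame({
        "chrom": "MT",
        "pos": positions[site_idx],
        "base": BASES[base_codes],
        "phred": phred,
        "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        "dist5": dist5,
        "dist3": dist3,
        "is_contaminant": is_contam,
    })
    diagnostics = pd.DataFrame({"pos": positions, "endogenous": endog,
                                "contaminant": contam})
    return MtReadSet(reads=reads, diagnostics=diagnostics)


def simulate_sex_counts(sex: str, config: SimulationConfig,
                        n_reads: int = 10_000, male_ry: float = 0.089,
                        xx_y_rate: float = 0.0) -> tuple[int, int]:
    """Simulate X- and Y-aligned read counts for an XX or XY individual.

    ``male_ry`` is the expected Y fraction nY/(nX+nY) for an XY sample
    (empirically ~0.089 for shotgun data); ``xx_y_rate`` models spurious
    Y-mapping for XX samples (0 in the error-free setting).
    Returns (n_x, n_y).
    """
    if sex not in ("XX", "XY"):
        raise ConfigError(f"sex must be 'XX' or 'XY', got {sex!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    ry = male_ry if sex == "XY" else xx_y_rate
    n_y = int(rng.binomial(n_reads, ry))
    return n_reads - n_y, n_y


def simulate_x_reads(config: SimulationConfig, n_sites: int = 2000,
                     depth: float = 5.0, allele_error: float = 0.001,
                     freq_law: tuple = ("uniform", 0.05, 0.95),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate reads over polymorphic X sites for a hemizygous male.

    The male carries a single X allele per site (drawn at the population
    frequency); with probability ``contamination_rate`` a read instead
    carries a contaminant allele drawn at the same frequency, and with
    probability ``allele_error`` a read's allele is flipped (the rate at
    which sequencing error converts one panel allele into the other).

    Returns ``(reads, sites)``: reads with columns pos and allele (0/1),
    sites with columns pos and freq (alternate-allele frequency).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    positions = np.sort(rng.choice(150_000_000, size=n_sites,
                                   replace=False)) + 1
    freqs = np.clip(draw_law(freq_law, n_sites, rng), 0.0, 1.0)
    true_allele = (rng.random(n_sites) < freqs).astype(np.uint8)

    counts = rng.poisson(depth, n_sites)
    site_idx = np.repeat(np.arange(n_sites), counts)
    n = site_idx.size
    is_contam = rng.random(n) < config.contamination_rate
    contam_allele = (rng.random(n) < freqs[site_idx]).astype(np.uint8)
    alleles = np.where(is_contam, contam_allele, true_allele[site_idx])
    flip = rng.random(n) < allele_error
    alleles = np.where(flip, 1 - alleles, alleles).astype(np.uint8)

    reads = pd.DataFrame({"pos": positions[site_idx], "allele": alleles})
    sites = pd.DataFrame({"pos": positions, "freq": freqs})
    return reads, sites


def simulate_modern_genotypes(n_pops: int = 2, n_per_pop: int = 50,
                              n_sites: int = 500, fst: float = 0.05,
                              ancestral_freq_law: tuple = ("uniform", 0.1, 0.9),
                              ancestral_freqs: np.ndarray | None = None,
                              seed: int = 0,
                              ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Simulate a modern reference genotype matrix with population structure.

    Population allele frequencies follow the Balding-Nichols model around a
    shared ancestral frequency with differentiation ``fst``; genotypes are
    Binomial(2, p_pop) dosages.

    Returns ``(genotypes, pop_freqs, labels)`` with genotypes shaped
    (n_pops * n_per_pop, n_sites) and pop_freqs (n_pops, n_sites).
    """
    rng = np.random.default_rng(seed)
    if ancestral_freqs is not None:
        p = np.clip(np.asarray(ancestral_freqs, dtype=float), 0.01, 0.99)
        n_sites = p.size
    else:
        p = np.clip(draw_law(ancestral_freq_law, n_sites, rng), 0.01, 0.99)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    pop_freqs = rng.beta(a, b, size=(n_pops, n_sites))
    genos = np.concatenate([
        rng.binomial(2, pop_freqs[k], size=(n_per_pop, n_sites))
        for k in range(n_pops)
    ]).astype(float)
    labels = [f"pop{k}" for k in range(n_pops) for _ in range(n_per_pop)]
    return genos, pop_freqs, labels
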