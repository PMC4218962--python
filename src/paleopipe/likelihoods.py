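"""Deamination-aware genotype likelihoods at panel sites.

Per-site likelihoods over the three diploid genotypes (ref/ref, ref/alt,
alt/alt) are computed from the read stack in linear space: for a read with
Phred quality Q the error probability is e = 10^(-Q/10); the read supports
an allele with likelihood 1-e if it matches, e/3 otherwise, and a genotype's
per-read likelihood is the mean of its two allele likelihoods.  Sites
spanned by no usable read receive the flat triple (1/3, 1/3, 1/3) and are
flagged uncovered.  Sites whose allele pair could be produced by cytosine
deamination (C/T or G/A) can be masked: in the default ``site-flat`` mode
the whole triple is reset to the flat value, deferring entirely to the
haplotype-copying prior; the alternate ``genotype-flat`` mode resets only
genotypes containing the damage-product allele and renormalizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ReferencePanel

FLAT = np.array([1 / 3, 1 / 3, 1 / 3])
MASK_MODES = ("site-flat", "genotype-flat")


@dataclass
class GLMatrix:
    """Per-site linear-space genotype likelihoods with QC flags.

    ``gl`` has shape (M, 3) in genotype order (ref/ref, ref/alt, alt/alt);
    every row is normalized to sum 1.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gl: np.ndarray
    uncovered: np.ndarray
    masked: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.positions,
            "ref": self.ref, "alt": self.alt,
            "gl_rr": self.gl[:, 0], "gl_ra": self.gl[:, 1],
            "gl_aa": self.gl[:, 2],
            "uncovered": self.uncovered.astype(int),
            "masked": self.masked.astype(int),
        })


def site_genotype_likelihoods(bases: np.ndarray, quals: np.ndarray,
                              ref_allele: str, alt_allele: str,
                              ) -> tuple[np.ndarray, bool]:
    """Likelihood triple for one site's read stack.

    Reads whose base is neither allele are discarded.  Returns the
    normalized (gl_rr, gl_ra, gl_aa) triple and an ``uncovered`` flag that
    is True when no usable read spans the site (flat triple emitted).
    """
    if ref_allele == alt_allele or len(ref_allele) != 1 or len(alt_allele) != 1:
        raise ValueError("alleles must be distinct single bases")
    bases = np.asarray(bases)
    quals = np.asarray(quals, dtype=float)
    if np.any(quals < 0):
        raise ValueError("negative Phred quality")
    keep = (bases == ref_allele) | (bases == alt_allele)
    bases, quals = bases[keep], quals[keep]
    if bases.size == 0:
        return FLAT.copy(), True
    e = 10.0 ** (-quals / 10.0)
    l_ref = np.where(bases == ref_allele, 1.0 - e, e / 3.0)
    l_alt = np.where(bases == alt_allele, 1.0 - e, e / 3.0)
    # log-space accumulation; per-read genotype likelihood is the mean of
    # the genotype's two allele likelihoods
    logs = np.array([
        np.log(l_ref).sum(),
        np.log(0.5 * (l_ref + l_alt)).sum(),
        np.log(l_alt).sum(),
    ])
    gl = np.exp(logs - logs.max())
    return gl / gl.sum(), False


def _is_deamination_pair(ref_allele: str, alt_allele: str) -> bool:
    return {ref_allele, alt_allele} in ({"C", "T"}, {"G", "A"})


def apply_deamination_mask(gl: GLMatrix, mode: str = "site-flat") -> GLMatrix:
    """Mask genotype likelihoods at deamination-prone (C/T, G/A) sites.

    ``site-flat`` resets the whole triple to (1/3, 1/3, 1/3); the genotype
    then rests on the copying prior alone.  ``genotype-flat`` resets only
    the genotypes containing the damage-product allele (T at C/T sites, A
    at G/A sites) to 1/3 before renormalizing.  Idempotent in both modes.
    """
    if mode not in MASK_MODES:
        raise ValueError(f"unknown mask mode {mode!r}")
    out = gl.gl.copy()
    masked = gl.masked.copy()
    for j in range(gl.n_sites):
        r, a = gl.ref[j], gl.alt[j]
        if masked[j] or not _is_deamination_pair(r, a):
            continue
        masked[j] = True
        if mode == "site-flat":
            out[j] = FLAT
        else:
            product = "T" if {r, a} == {"C", "T"} else "A"
            triple = out[j].copy()
            # genotypes containing the damage-product allele
            affected = [i for i, g in enumerate(((r, r), (r, a), (a, a)))
                        if product in g]
            triple[affected] = 1 / 3
            out[j] = triple / triple.sum()
    return GLMatrix(chrom=gl.chrom, positions=gl.positions, ref=gl.ref,
                    alt=gl.alt, gl=out, uncovered=gl.uncovered.copy(),
                    masked=masked)


def build_gl_matrix(reads: pd.DataFrame, panel: ReferencePanel,
                    mode: str = "site-flat") -> GLMatrix:
    """Genotype likelihoods at every panel site, with deamination masking.

    Sites absent from the read table emit the flat triple and the uncovered
    flag.  A read position that is not a panel site raises ValueError.
    """
    if mode not in MASK_MODES:
        raise ValueError(f"unknown mask mode {mode!r}")
    M = panel.n_sites
    gl = np.tile(FLAT, (M, 1))
    uncovered = np.ones(M, dtype=bool)
    masked = np.zeros(M, dtype=bool)

    pos_index = {int(p): j for j, p in enumerate(panel.positions)}
    if len(reads):
        unknown = set(map(int, reads["pos"])) - pos_index.keys()
        if unknown:
            raise ValueError(
                f"reads at {len(unknown)} positions absent from the panel "
                f"(e.g. {sorted(unknown)[:3]})")
        for pos, grp in reads.groupby("pos", sort=False):
            j = pos_index[int(pos)]
            triple, unc = site_genotype_likelihoods(
                grp["base"].to_numpy(), grp["phred"].to_numpy(),
                panel.ref[j], panel.alt[j])
            gl[j] = triple
            uncovered[j] = unc
    out = GLMatrix(chrom=panel.chrom, positions=panel.positions.copy(),
                   ref=panel.ref.copy(), alt=panel.alt.copy(), gl=gl,
                   uncovered=uncovered, masked=masked)
    return apply_deamination_mask(out, mode=mode)


def downsample(reads: pd.DataFrame, fraction: float | None = None,
               target_coverage: float | None = None,
               current_coverage: float | None = None,
               seed: int = 0) -> pd.DataFrame:
    """Thin a read table, keeping each read independently.

    Either ``fraction`` in (0, 1] or ``target_coverage`` (with
    ``current_coverage``) must be given.  Deterministic under ``seed``.
    """
    if fraction is None:
        if target_coverage is None or current_coverage is None:
            raise ValueError("give fraction, or target and current coverage")
        fraction = target_coverage / current_coverage
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if fraction == 1.0:
        return reads.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return reads.loc[keep].reset_index(drop=True)
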