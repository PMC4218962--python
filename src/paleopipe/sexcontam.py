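"""Sex determination and contamination estimation.

Genetic sex is called from the fraction of sex-chromosome reads aligning to
Y (the Ry statistic, nY/(nX+nY)): XX individuals give Ry near 0, XY
individuals near the male expectation, with a normal-approximation binomial
confidence interval deciding between the two.  Contamination is estimated
two ways: from mtDNA reads at diagnostic positions where the endogenous
consensus differs from a candidate contaminant haplotype, and — for male
samples — from apparent heterozygosity across polymorphic X sites, where a
hemizygous X should carry a single allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Ry decision bounds from the shotgun sex-typing literature: call XX when
# the CI upper bound sits below 0.016, XY when the lower bound exceeds 0.075.
UPPER_XX_BOUND = 0.016
LOWER_XY_BOUND = 0.075


@dataclass
class SexCall:
    n_x: int
    n_y: int
    ry: float
    ci_low: float
    ci_high: float
    call: str  # "XX" | "XY" | "indeterminate"


@dataclass
class ContaminationEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    method: str  # "mtDNA" | "X"
    n_informative: int


def determine_sex(n_x: int, n_y: int,
                  upper_xx_bound: float = UPPER_XX_BOUND,
                  lower_xy_bound: float = LOWER_XY_BOUND) -> SexCall:
    """Call genetic sex from X- and Y-aligned read counts."""
    n = n_x + n_y
    if n <= 0:
        raise ValueError("no sex-chromosome reads")
    ry = n_y / n
    se = np.sqrt(ry * (1 - ry) / n)
    lo, hi = max(0.0, ry - 1.96 * se), min(1.0, ry + 1.96 * se)
    if hi < upper_xx_bound:
        call = "XX"
    elif lo > lower_xy_bound:
        call = "XY"
    else:
        call = "indeterminate"
    return SexCall(n_x=n_x, n_y=n_y, ry=ry, ci_low=lo, ci_high=hi, call=call)


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    p = k / n
    se = np.sqrt(p * (1 - p) / n)
    return max(0.0, p - 1.96 * se), min(1.0, p + 1.96 * se)


def mt_contamination(mt_reads: pd.DataFrame, diagnostics: pd.DataFrame,
                     exclude_damage_consistent: bool = True,
                     ) -> ContaminationEstimate:
    """Contaminant read fraction at mtDNA diagnostic positions.

    Counts reads carrying the contaminant allele among reads carrying
    either allele at each diagnostic position.  When
    ``exclude_damage_consistent`` is on (default), read observations whose
    apparent contaminant support could equally be deamination — the
    observed base is T at an endogenous-C position, or A at an
    endogenous-G position — are dropped from numerator and denominator,
    so transition-diagnostic positions contribute only their unambiguous
    reads.
    """
    diag = diagnostics.set_index("pos")
    sub = mt_reads[mt_reads["pos"].isin(diag.index)]
    if not len(sub):
        raise ValueError("no covered diagnostic positions")
    endog = sub["pos"].map(diag["endogenous"]).to_numpy()
    contam = sub["pos"].map(diag["contaminant"]).to_numpy()
    base = sub["base"].to_numpy()

    usable = (base == endog) | (base == contam)
    if exclude_damage_consistent:
        damage_like = (((endog == "C") & (base == "T"))
                       | ((endog == "G") & (base == "A")))
        usable &= ~damage_like
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no usable reads at diagnostic positions")
    k = int(((base == contam) & usable).sum())
    lo, hi = _binom_ci(k, n)
    return ContaminationEstimate(estimate=k / n, ci_low=lo, ci_high=hi,
                                 method="mtDNA", n_informative=n)


def x_contamination(x_reads: pd.DataFrame, x_sites: pd.DataFrame,
                    autosomal_error_rate: float,
                    min_depth: int = 2, n_min_sites: int = 100,
                    n_bootstrap: int = 200, seed: int = 0,
                    ) -> ContaminationEstimate:
    """Moment-based contamination estimate from male X polymorphisms.

    A male's X is hemizygous, so reads disagreeing with a site's majority
    allele reflect error or contamination.  With d_poly the disagreeing
    read fraction over polymorphic X sites of depth >= ``min_depth``, the
    estimate is max(0, (d_poly - autosomal_error_rate) / h_bar), where
    h_bar is the mean of 2 p (1 - p) over used sites — the chance a
    contaminant read carries the non-sample allele.  The CI is a
    site-level bootstrap.

    ``x_reads`` needs columns pos and allele (0/1); ``x_sites`` columns
    pos and freq (alternate-allele frequency).
    """
    freqs = x_sites.set_index("pos")["freq"]
    poly = freqs[(freqs > 0) & (freqs < 1)]
    sub = x_reads[x_reads["pos"].isin(poly.index)]
    counts = sub.groupby("pos")["allele"].agg(["size", "sum"])
    counts = counts[counts["size"] >= min_depth]
    if len(counts) < n_min_sites:
        raise ValueError(
            f"too few informative sites ({len(counts)} < {n_min_sites})")

    n_alt = counts["sum"].to_numpy(dtype=float)
    depth = counts["size"].to_numpy(dtype=float)
    minority = np.minimum(n_alt, depth - n_alt)  # reads off the majority
    p = poly.loc[counts.index].to_numpy()
    h = 2 * p * (1 - p)

    def estimate(idx: np.ndarray) -> float:
        d_poly = minority[idx].sum() / depth[idx].sum()
        return max(0.0, (d_poly - autosomal_error_rate) / h[idx].mean())

    all_idx = np.arange(len(counts))
    est = estimate(all_idx)
    rng = np.random.default_rng(seed)
    boots = np.array([
        estimate(rng.integers(0, len(counts), len(counts)))
        for _ in range(n_bootstrap)
    ])
    lo, hi = np.quantile(boots, [0.025, 0.975])
    lo, hi = min(lo, est), max(hi, est)
    return ContaminationEstimate(estimate=float(np.clip(est, 0.0, 1.0)),
                                 ci_low=float(lo), ci_high=float(hi),
                                 method="X", n_informative=int(len(counts)))
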