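"""Runs of homozygosity: sliding-window detection, length classes, ageing.

Detection follows the PLINK-style window heuristic: windows of
``window_snps`` consecutive SNPs count as homozygous when they contain at
most ``max_het_per_window`` heterozygous and ``max_missing_per_window``
missing calls; a SNP is inside a run when the fraction of spanning windows
that are homozygous reaches ``hit_proportion``; maximal in-run stretches
are split at physical gaps above ``max_gap_kb`` and filtered by minimum
length and SNP count.  Segments are classed short/long at 1.6 Mb: a
genome-wide excess of long runs indicates recent endogamy, an excess of
short runs a restricted ancestral population size.  Total per-sample ROH
is regressed on sample age to expose temporal trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ROHConfig:
    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    hit_proportion: float = 0.05
    min_length_kb: float = 500.0
    min_snps: int = 50
    max_gap_kb: float = 1000.0
    class_threshold_mb: float = 1.6

    def validate(self) -> None:
        for name in ("window_snps", "hit_proportion", "min_length_kb",
                     "min_snps", "max_gap_kb", "class_threshold_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHSegment:
    """Homozygous run; coordinates 1-based inclusive, length = end-start+1."""

    chrom: str
    start: int
    end: int
    n_snps: int
    roh_class: str  # "short" | "long"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length / 1e6


def _segment_class(length_bp: int, config: ROHConfig) -> str:
    # lengths exactly at the threshold are classed long
    return "long" if length_bp >= config.class_threshold_mb * 1e6 else "short"


def in_run_mask(genotypes: np.ndarray, config: ROHConfig) -> np.ndarray:
    """Per-SNP in-run indicator from the sliding-window heuristic.

    ``genotypes`` are dosages in {0, 1, 2} with -1 for missing calls.
    """
    g = np.asarray(genotypes)
    M = g.size
    W = config.window_snps
    if M < W:
        return np.zeros(M, dtype=bool)
    het = (g == 1).astype(np.int64)
    mis = (g < 0).astype(np.int64)
    # window s covers SNPs [s, s+W-1]
    csum_h = np.concatenate([[0], np.cumsum(het)])
    csum_m = np.concatenate([[0], np.cumsum(mis)])
    wh = csum_h[W:] - csum_h[:-W]
    wm = csum_m[W:] - csum_m[:-W]
    hom_win = ((wh <= config.max_het_per_window)
               & (wm <= config.max_missing_per_window)).astype(np.int64)
    n_win = hom_win.size  # = M - W + 1
    csum_w = np.concatenate([[0], np.cumsum(hom_win)])
    idx = np.arange(M)
    lo = np.maximum(0, idx - W + 1)
    hi = np.minimum(idx, n_win - 1)
    spanning = hi - lo + 1
    hits = csum_w[hi + 1] - csum_w[lo]
    return hits / spanning >= config.hit_proportion


def detect_roh(genotypes: np.ndarray, positions: np.ndarray,
               config: ROHConfig = ROHConfig(),
               chrom: str = "1") -> list[ROHSegment]:
    """Detect runs of homozygosity on one chromosome.

    Positions must be sorted ascending; dosages in {0,1,2} with -1 missing.
    """
    config.validate()
    positions = np.asarray(positions)
    g = np.asarray(genotypes)
    if positions.size != g.size:
        raise ValueError("genotypes and positions differ in length")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    mask = in_run_mask(g, config)

    segments: list[ROHSegment] = []
    i = 0
    M = mask.size
    while i < M:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < M and mask[j + 1]:
            j += 1
        # split the stretch [i, j] at physical gaps above max_gap_kb
        start = i
        for k in range(i, j + 1):
            split = (k == j or positions[k + 1] - positions[k]
                     > config.max_gap_kb * 1000)
            if split:
                seg_len = int(positions[k] - positions[start] + 1)
                n_snps = k - start + 1
                if (seg_len >= config.min_length_kb * 1000
                        and n_snps >= config.min_snps):
                    segments.append(ROHSegment(
                        chrom=chrom, start=int(positions[start]),
                        end=int(positions[k]), n_snps=n_snps,
                        roh_class=_segment_class(seg_len, config)))
                start = k + 1
        i = j + 1
    return segments


def classify_and_total(segments: list[ROHSegment],
                       config: ROHConfig = ROHConfig()) -> dict[str, float]:
    """Total Mb of short and long ROH (boundary length counts as long)."""
    short = sum(s.length for s in segments
                if _segment_class(s.length, config) == "short")
    long_ = sum(s.length for s in segments
                if _segment_class(s.length, config) == "long")
    return {"short_mb": short / 1e6, "long_mb": long_ / 1e6,
            "total_mb": (short + long_) / 1e6}


def roh_age_regression(total_roh_mb: np.ndarray, age_median: np.ndarray
                       ) -> dict[str, float]:
    """OLS of per-sample total ROH (Mb) on sample age (median, cal BC).

    Returns slope, intercept, r_squared and the two-sided slope p-value.
    """
    y = np.asarray(total_roh_mb, dtype=float)
    x = np.asarray(age_median, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ages")
    if np.ptp(y) == 0:
        # constant response: flat fit explains nothing
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0,
                "p_value": 1.0}
    res = stats.linregress(x, y)
    return {"slope": res.slope, "intercept": res.intercept,
            "r_squared": res.rvalue ** 2, "p_value": res.pvalue}


def segments_to_bed(segments: list[ROHSegment]) -> pd.DataFrame:
    """0-based half-open BED frame mirroring the 1-based segment table."""
    return pd.DataFrame({
        "chrom": [s.chrom for s in segments],
        "start": [s.start - 1 for s in segments],
        "end": [s.end for s in segments],
        "name": [s.roh_class for s in segments],
    })


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [s.chrom for s in segments],
        "start": [s.start for s in segments],
        "end": [s.end for s in segments],
        "length_bp": [s.length for s in segments],
        "n_snps": [s.n_snps for s in segments],
        "roh_class": [s.roh_class for s in segments],
    })
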