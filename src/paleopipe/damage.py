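"""Endogenous-content accounting and post-mortem damage profiling.

Authentic ancient DNA shows elevated C->T substitution toward 5' read ends
(and G->A toward 3' ends, the same lesion on the complementary strand),
decaying roughly exponentially with distance from the terminus, plus short
fragment lengths.  This module computes those diagnostics from per-site
read observations and summarizes the decay with an exponential fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

NO_DECAY_LAMBDA = 1e3  # fitted decay lengths beyond this flag a flat profile


def endogenous_fraction(n_mapped_nonclonal: int, n_total: int) -> float:
    """Percentage of non-clonal reads mapping to the target genome."""
    if n_total <= 0:
        raise ValueError("total read count must be positive")
    if n_mapped_nonclonal > n_total or n_mapped_nonclonal < 0:
        raise ValueError("mapped non-clonal count outside [0, total]")
    return 100.0 * n_mapped_nonclonal / n_total


@dataclass
class DamageProfile:
    """Terminal substitution rates by distance from each read end.

    ct_rate_5p[i-1] is the C->T rate among reads spanning reference-C sites
    at distance i from the 5' end (i = 1..P); ga_rate_3p analogous for G->A
    and the 3' end.  Positions with zero denominator carry NaN rate and are
    listed in ``undefined_positions`` rather than propagated silently.
    """

    ct_rate_5p: np.ndarray
    ga_rate_3p: np.ndarray
    ct_counts: np.ndarray  # (P, 2) numerator, denominator
    ga_counts: np.ndarray
    fragment_length_hist: pd.Series
    p_max: int

    @property
    def undefined_positions(self) -> dict:
        return {
            "5p": (np.flatnonzero(self.ct_counts[:, 1] == 0) + 1).tolist(),
            "3p": (np.flatnonzero(self.ga_counts[:, 1] == 0) + 1).tolist(),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.p_max):
            rows.append({"position": i + 1, "end": "5p",
                         "numerator": int(self.ct_counts[i, 0]),
                         "denominator": int(self.ct_counts[i, 1]),
                         "rate": self.ct_rate_5p[i]})
            rows.append({"position": i + 1, "end": "3p",
                         "numerator": int(self.ga_counts[i, 0]),
                         "denominator": int(self.ga_counts[i, 1]),
                         "rate": self.ga_rate_3p[i]})
        return pd.DataFrame(rows)


def damage_profile(reads: pd.DataFrame, site_alleles: dict[int, str],
                   p_max: int = 25,
                   bases_read_oriented: bool = False) -> DamageProfile:
    """Count terminal C->T and G->A substitution rates.

    ``site_alleles`` maps position to the reference (panel) allele; only
    reference-C sites enter the 5' C->T denominators and reference-G sites
    the 3' G->A denominators — other mismatches belong to error estimation,
    not damage.  Set ``bases_read_oriented`` when minus-strand bases are
    stored in read orientation; they are then complement-normalized before
    counting (the synthetic generator writes reference-oriented bases).
    """
    ct = np.zeros((p_max, 2), dtype=np.int64)
    ga = np.zeros((p_max, 2), dtype=np.int64)
    if len(reads):
        ref = reads["pos"].map(site_alleles)
        known = ref.notna()
        sub = reads.loc[known]
        ref = ref[known].to_numpy()
        base = sub["base"].to_numpy().astype("<U1")
        if bases_read_oriented:
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            neg = (sub["strand"] == "-").to_numpy()
            base = np.where(neg, [comp[b] for b in base], base)
        d5 = sub["dist5"].to_numpy()
        d3 = sub["dist3"].to_numpy()

        c_sites = ref == "C"
        for i in range(1, p_max + 1):
            at = c_sites & (d5 == i)
            ct[i - 1, 1] = at.sum()
            ct[i - 1, 0] = (at & (base == "T")).sum()
        g_sites = ref == "G"
        for i in range(1, p_max + 1):
            at = g_sites & (d3 == i)
            ga[i - 1, 1] = at.sum()
            ga[i - 1, 0] = (at & (base == "A")).sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        ct_rate = np.where(ct[:, 1] > 0, ct[:, 0] / np.maximum(ct[:, 1], 1),
                           np.nan)
        ga_rate = np.where(ga[:, 1] > 0, ga[:, 0] / np.maximum(ga[:, 1], 1),
                           np.nan)
    if len(reads):
        lengths = (reads["dist5"] + reads["dist3"] - 1)
        hist = lengths.value_counts().sort_index()
    else:
        hist = pd.Series(dtype=np.int64)
    return DamageProfile(ct_rate_5p=ct_rate, ga_rate_3p=ga_rate,
                         ct_counts=ct, ga_counts=ga,
                         fragment_length_hist=hist, p_max=p_max)


@dataclass
class DecayFit:
    """Exponential damage-decay fit rate(i) = A * exp(-(i-1)/lam)."""

    amplitude: float
    decay_constant: float
    rss: float
    flag: str = "ok"  # "ok" | "all-zero" | "no decay detected"


def fit_decay(rates: np.ndarray) -> DecayFit:
    """Least-squares exponential fit of a terminal substitution profile.

    ``rates`` is the per-position rate vector (position 1 first); NaN
    positions are dropped.  At least 3 defined positions are required.
    All-zero profiles return amplitude 0 with an undefined decay constant;
    essentially flat profiles are flagged "no decay detected".
    """
    rates = np.asarray(rates, dtype=float)
    pos = np.arange(1, rates.size + 1)
    ok = np.isfinite(rates)
    pos, rates = pos[ok], rates[ok]
    if rates.size < 3:
        raise ValueError("need >= 3 positions with defined rates")
    if np.all(rates == 0):
        return DecayFit(amplitude=0.0, decay_constant=float("nan"),
                        rss=0.0, flag="all-zero")

    def model(i, amp, lam):
        return amp * np.exp(-(i - 1) / lam)

    p0 = (max(rates[0], 1e-3), 3.0)
    try:
        popt, _ = curve_fit(model, pos, rates, p0=p0,
                            bounds=([0.0, 1e-3], [1.0, 1e6]), maxfev=10000)
    except RuntimeError:
        popt = p0
    amp, lam = float(popt[0]), float(popt[1])
    rss = float(((rates - model(pos, amp, lam)) ** 2).sum())
    flag = "no decay detected" if lam > NO_DECAY_LAMBDA else "ok"
    return DecayFit(amplitude=amp, decay_constant=lam, rss=rss, flag=flag)


def merge_profiles(a: DamageProfile, b: DamageProfile) -> DamageProfile:
    """Count-weighted merge of two profiles over the same position range."""
    if a.p_max != b.p_max:
        raise ValueError("profiles track different position ranges")
    ct = a.ct_counts + b.ct_counts
    ga = a.ga_counts + b.ga_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        ct_rate = np.where(ct[:, 1] > 0, ct[:, 0] / np.maximum(ct[:, 1], 1),
                           np.nan)
        ga_rate = np.where(ga[:, 1] > 0, ga[:, 0] / np.maximum(ga[:, 1], 1),
                           np.nan)
    hist = a.fragment_length_hist.add(b.fragment_length_hist, fill_value=0)
    return DamageProfile(ct_rate_5p=ct_rate, ga_rate_3p=ga_rate,
                         ct_counts=ct, ga_counts=ga,
                         fragment_length_hist=hist.astype(np.int64),
                         p_max=a.p_max)
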