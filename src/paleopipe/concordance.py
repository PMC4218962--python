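"""Imputation validation: downsample, impute, compare with truth.

Mirrors the validation a palaeogenomic study performs on its high-coverage
genomes: subsample reads to a grid of coverages, impute against the phased
panel, and measure call rate and concordance with the directly observed
(here: simulated-truth) genotypes at a genotype-probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impute import CalledGenotypes, HMMParams, call_genotypes, forward_backward
from .likelihoods import build_gl_matrix
from .simulate import DiploidTruth, ReferencePanel, SimulationConfig, simulate_reads


@dataclass
class ConcordanceReport:
    """Call-rate/concordance summary at one threshold.

    het_concordance conditions on truth-heterozygous called loci (the
    fraction called heterozygous-and-matching); het_concordance_callcond is
    the alternate conditioning on call-heterozygous loci.
    nonref_discordance is the mismatch fraction among called loci where
    truth or call is non-reference.
    """

    threshold: float
    n_loci: int
    call_rate: float
    overall_concordance: float
    het_concordance: float
    het_concordance_callcond: float
    nonref_discordance: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "n_loci": self.n_loci,
            "call_rate": self.call_rate,
            "overall": self.overall_concordance,
            "het": self.het_concordance,
            "het_callcond": self.het_concordance_callcond,
            "nonref_disc": self.nonref_discordance,
        }


def _safe_frac(num: float, den: float) -> float:
    return float(num / den) if den > 0 else float("nan")


def concordance(calls: CalledGenotypes, truth: np.ndarray,
                threshold: float | None = None) -> ConcordanceReport:
    """Compare thresholded calls against a truth dosage vector.

    Truth-missing loci (dosage < 0) are excluded from every denominator.
    """
    truth = np.asarray(truth)
    if truth.shape[0] != calls.genotypes.shape[0]:
        raise ValueError("call and truth site sets differ")
    thr = calls.threshold if threshold is None else threshold
    evaluable = truth >= 0
    g_true = truth[evaluable]
    g_call = calls.genotypes[evaluable]
    called = g_call >= 0
    n_called = int(called.sum())

    match = called & (g_call == g_true)
    truth_het_called = called & (g_true == 1)
    call_het = called & (g_call == 1)
    nonref = called & ((g_true != 0) | (g_call != 0))

    return ConcordanceReport(
        threshold=thr,
        n_loci=int(evaluable.sum()),
        call_rate=_safe_frac(n_called, evaluable.sum()),
        overall_concordance=_safe_frac(match.sum(), n_called),
        het_concordance=_safe_frac((truth_het_called & match).sum(),
                                   truth_het_called.sum()),
        het_concordance_callcond=_safe_frac((call_het & match).sum(),
                                            call_het.sum()),
        nonref_discordance=_safe_frac((nonref & ~match).sum(), nonref.sum()),
    )


def impute_at_coverage(truth: DiploidTruth, panel: ReferencePanel,
                       config: SimulationConfig, coverage: float,
                       thresholds: tuple[float, ...] = (0.99,),
                       params: HMMParams = HMMParams(),
                       mask_mode: str = "site-flat",
                       ) -> list[ConcordanceReport]:
    """Simulate reads at one coverage, impute, report per threshold."""
    reads = simulate_reads(truth, panel, config.with_(coverage=coverage))
    gl = build_gl_matrix(reads, panel, mode=mask_mode)
    post = forward_backward(gl, panel, params)
    return [concordance(call_genotypes(post, t), truth.genotypes)
            for t in thresholds]


def coverage_sweep(truth: DiploidTruth, panel: ReferencePanel,
                   config: SimulationConfig,
                   coverages: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0),
                   thresholds: tuple[float, ...] = (0.99, 0.85),
                   params: HMMParams = HMMParams(),
                   n_reps: int = 10, seed: int = 0,
                   mask_mode: str = "site-flat") -> pd.DataFrame:
    """Coverage x threshold x replicate concordance table (tidy rows).

    Each replicate re-simulates the read layer with a fresh derived seed;
    the truth and panel are held fixed.
    """
    if list(coverages) != sorted(coverages) or min(coverages) <= 0:
        raise ValueError("coverages must be positive ascending")
    rows = []
    for cov in coverages:
        for rep in range(n_reps):
            rep_cfg = config.with_(
                coverage=cov,
                seed=int(np.random.SeedSequence(
                    [seed, rep, int(cov * 1000)]).generate_state(1)[0]
                    % (2 ** 31)),
            )
            reports = impute_at_coverage(truth, panel, rep_cfg, cov,
                                         thresholds, params, mask_mode)
            for rpt in reports:
                row = {"coverage": cov, "replicate": rep}
                row.update(rpt.to_dict())
                rows.append(row)
    return pd.DataFrame(rows)
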