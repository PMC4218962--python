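"""Trait-SNP genotyping from imputed posteriors and temporal tabulation.

Single-locus calls use a relaxed genotype-probability threshold (0.85 by
default) compared with genome-wide analyses, reflecting that a handful of
pre-specified loci tolerate a higher per-call error rate.  The default
trait panel covers the European pigmentation sweeps (rs1426654 in SLC24A5,
rs16891982 in SLC45A2, rs2733831 in TYRP1) and the lactase-persistence T
allele at rs4988235; phenotype *prediction* systems remain pluggable — an
external coefficient table can be registered but none is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .impute import GenotypePosterior

SINGLE_LOCUS_THRESHOLD = 0.85

#: European selective-sweep loci tracked by default (GRCh37 positions).
DEFAULT_TRAIT_PANEL = pd.DataFrame([
    {"rsid": "rs1426654", "chrom": "15", "pos": 48426484, "gene": "SLC24A5",
     "effect_allele": "A", "trait": "light skin pigmentation"},
    {"rsid": "rs16891982", "chrom": "5", "pos": 33951693, "gene": "SLC45A2",
     "effect_allele": "G", "trait": "light skin pigmentation"},
    {"rsid": "rs2733831", "chrom": "9", "pos": 12694682, "gene": "TYRP1",
     "effect_allele": "G", "trait": "hair/iris pigmentation"},
    {"rsid": "rs4988235", "chrom": "2", "pos": 136608646, "gene": "MCM6/LCT",
     "effect_allele": "T", "trait": "lactase persistence"},
])


def load_trait_panel(path) -> pd.DataFrame:
    """Read a trait panel TSV (rsid, chrom, pos, effect_allele, gene, trait)."""
    panel = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if panel["rsid"].duplicated().any():
        raise ValueError("duplicate rsids in trait panel")
    return panel


def extract_trait_genotypes(posterior: GenotypePosterior,
                            site_ref: np.ndarray, site_alt: np.ndarray,
                            traits: pd.DataFrame,
                            threshold: float = SINGLE_LOCUS_THRESHOLD,
                            ) -> pd.DataFrame:
    """Call trait-locus genotypes from an imputed posterior.

    Loci absent from the posterior's site set are reported with status
    "absent".  Effect-allele dosage is oriented by the locus's effect
    allele (alt dosage if effect == alt, flipped if effect == ref, and
    flagged "allele-mismatch" otherwise); -1 encodes no-call.
    """
    if not (1 / 3 < threshold <= 1.0):
        raise ValueError("threshold must be in (1/3, 1]")
    pos_index = {int(p): j for j, p in enumerate(posterior.positions)}
    rows = []
    for _, locus in traits.iterrows():
        row = {"rsid": locus["rsid"], "gene": locus.get("gene", ""),
               "effect_allele": locus["effect_allele"],
               "status": "called", "gp_max": np.nan,
               "genotype": -1, "effect_dosage": -1}
        j = pos_index.get(int(locus["pos"]))
        if j is None:
            row["status"] = "absent"
            rows.append(row)
            continue
        gp = posterior.gp[j]
        best = float(gp.max())
        row["gp_max"] = best
        if best < threshold or (gp == best).sum() > 1:
            row["status"] = "no-call"
            rows.append(row)
            continue
        g = int(gp.argmax())  # alt dosage
        row["genotype"] = g
        eff = locus["effect_allele"]
        if eff == site_alt[j]:
            row["effect_dosage"] = g
        elif eff == site_ref[j]:
            row["effect_dosage"] = 2 - g
        else:
            row["status"] = "allele-mismatch"
            row["effect_dosage"] = -1
        rows.append(row)
    return pd.DataFrame(rows)


def trait_trajectory(reports: dict[str, pd.DataFrame],
                     sample_ages: dict[str, float]) -> pd.DataFrame:
    """Tabulate effect-allele dosages by locus across age-ordered samples.

    ``reports`` maps sample name to its per-locus report; ``sample_ages``
    to median age (cal BC, larger = older).  Returns a tidy table ordered
    oldest-first with per-locus first-appearance and first-homozygote
    summaries among called genotypes.
    """
    if not reports:
        raise ValueError("need >= 1 sample")
    order = sorted(reports, key=lambda s: -sample_ages[s])
    rows = []
    for sample in order:
        rpt = reports[sample].set_index("rsid")
        for rsid, locus in rpt.iterrows():
            rows.append({
                "sample": sample, "age": sample_ages[sample], "rsid": rsid,
                "effect_dosage": (int(locus["effect_dosage"])
                                  if locus["status"] == "called" else -1),
            })
    tidy = pd.DataFrame(rows)

    summaries = []
    for rsid, grp in tidy.groupby("rsid", sort=False):
        grp = grp.sort_values("age", ascending=False)
        called = grp[grp["effect_dosage"] >= 0]
        appear = called[called["effect_dosage"] >= 1]
        homo = called[called["effect_dosage"] == 2]
        summaries.append({
            "rsid": rsid,
            "first_appearance_sample":
                appear.iloc[0]["sample"] if len(appear) else "",
            "first_appearance_age":
                appear.iloc[0]["age"] if len(appear) else np.nan,
            "first_homozygote_sample":
                homo.iloc[0]["sample"] if len(homo) else "",
            "first_homozygote_age":
                homo.iloc[0]["age"] if len(homo) else np.nan,
        })
    tidy.attrs["summary"] = pd.DataFrame(summaries)
    return tidy


class PhenotypePredictor:
    """Pluggable interface for external phenotype-prediction systems.

    Published forensic prediction models (HirisPlex-style) ship their own
    coefficient tables; register one here as a callable over effect-allele
    dosages.  The package bundles no coefficients and ships no default
    prediction — only genotypes and dosages are reported out of the box.
    """

    def __init__(self):
        self._models: dict[str, Callable[[dict[str, int]], dict]] = {}

    def register(self, name: str,
                 model: Callable[[dict[str, int]], dict]) -> None:
        self._models[name] = model

    def predict(self, name: str, dosages: dict[str, int]) -> dict:
        if name not in self._models:
            raise KeyError(f"no phenotype model registered as {name!r}")
        return self._models[name](dosages)
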