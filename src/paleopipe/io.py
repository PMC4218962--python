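"""Readers and writers for the pipeline's on-disk interfaces.

Reference panels travel as minimal phased VCF (read back through cyvcf2),
read observations and reports as plain TSV, configs as YAML.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import ReferencePanel, READ_COLUMNS


def write_panel_vcf(panel: ReferencePanel, path: str | os.PathLike) -> None:
    """Write a phased panel as a minimal VCF with K/2 diploid samples.

    Haplotypes 2i and 2i+1 become sample i's phased genotype "a|b".
    """
    K = panel.n_haplotypes
    if K % 2:
        raise ValueError("panel must hold an even number of haplotypes")
    samples = [f"HAP{i:04d}" for i in range(K // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        H = panel.haplotypes
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(K // 2)
            )
            fh.write(f"{panel.chrom}\t{panel.positions[j]}\t.\t"
                     f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_panel_vcf(path: str | os.PathLike) -> ReferencePanel:
    """Load a phased biallelic panel from VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    positions, ref, alt, columns = [], [], [], []
    chrom = None
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"site {var.POS} is not biallelic")
        chrom = var.CHROM
        positions.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # genotype.array(): one row per sample, [allele_a, allele_b, phased]
        g = var.genotype.array()
        columns.append(g[:, :2].reshape(-1))
    vcf.close()
    haps = np.asarray(columns, dtype=np.uint8).T
    return ReferencePanel(chrom=chrom, positions=np.asarray(positions),
                          ref=np.asarray(ref), alt=np.asarray(alt),
                          haplotypes=haps)


def write_reads_tsv(reads: pd.DataFrame, path: str | os.PathLike,
                    keep_hidden: bool = False) -> None:
    """Write read observations as TSV (hidden truth columns dropped)."""
    cols = list(reads.columns) if keep_hidden else [
        c for c in READ_COLUMNS if c in reads.columns]
    reads[cols].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "base": str,
                                              "strand": str})


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Deterministic TSV output (fixed float formatting)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
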