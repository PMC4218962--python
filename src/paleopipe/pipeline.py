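"""End-to-end pipeline wiring: simulate -> QC -> impute -> analyze.

Every stage reads its inputs from, and writes its reports to, the run's
output directory, so any stage can be re-run standalone with identical
results; a manifest records the seed and full parameter echo.  Stage
failures surface with the failing stage named while earlier outputs are
retained.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import concordance, coverage_sweep
from .config import PipelineConfig
from .damage import damage_profile, endogenous_fraction, fit_decay
from .impute import call_genotypes, forward_backward
from .io import (read_panel_vcf, read_reads_tsv, write_panel_vcf,
                 write_reads_tsv, write_tsv)
from .likelihoods import GLMatrix, build_gl_matrix
from .pca import cosample_project, reference_pca
from .roh import classify_and_total, detect_roh, roh_age_regression, \
    segments_to_bed, segments_to_frame
from .sexcontam import determine_sex, mt_contamination, x_contamination
from .simulate import (simulate_invariant_reads, simulate_mt_reads,
                       simulate_modern_genotypes,
                       simulate_panel, simulate_reads, simulate_sex_counts,
                       simulate_truth, simulate_x_reads)
from .traits import extract_trait_genotypes, trait_trajectory

log = logging.getLogger("paleopipe")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(cfg: PipelineConfig) -> None:
    """Generate every input: panel, truths, reads, mtDNA, sex, X, moderns."""
    out = _out(cfg)
    sim = cfg.simulation.with_(seed=cfg.stage_seed("simulate"))
    panel = simulate_panel(sim)
    write_panel_vcf(panel, out / "panel.vcf")

    rng = np.random.default_rng(cfg.stage_seed("simulate", 999))
    endo_rows = []
    for s in range(cfg.n_samples):
        s_cfg = sim.with_(seed=cfg.stage_seed("simulate", s + 1),
                          founder_count=cfg.sample_founder_counts[s])
        truth = simulate_truth(panel, s_cfg)
        write_tsv(pd.DataFrame({
            "pos": panel.positions, "hap_a": truth.hap_a,
            "hap_b": truth.hap_b, "genotype": truth.genotypes,
        }), out / f"truth_{s}.tsv")
        reads = simulate_reads(truth, panel, s_cfg)
        write_reads_tsv(reads, out / f"reads_{s}.tsv")

        dmg_reads, dmg_sites = simulate_invariant_reads(
            s_cfg.with_(coverage=cfg.damage_coverage),
            n_sites=cfg.damage_n_sites)
        write_reads_tsv(dmg_reads, out / f"damage_reads_{s}.tsv")
        write_tsv(pd.DataFrame({"pos": list(dmg_sites.keys()),
                                "ref": list(dmg_sites.values())}),
                  out / f"damage_sites_{s}.tsv")

        mt = simulate_mt_reads(s_cfg, n_diagnostic=cfg.mt_n_diagnostic,
                               depth=cfg.mt_depth)
        write_reads_tsv(mt.reads, out / f"mt_reads_{s}.tsv")
        write_tsv(mt.diagnostics, out / f"mt_diagnostics_{s}.tsv")

        x_reads, x_sites = simulate_x_reads(
            s_cfg, n_sites=cfg.x_n_sites, depth=cfg.x_depth,
            allele_error=cfg.x_allele_error)
        write_tsv(x_reads, out / f"x_reads_{s}.tsv")
        write_tsv(x_sites, out / f"x_sites_{s}.tsv")

        n_mapped = int(rng.binomial(cfg.n_shotgun_reads, cfg.endogenous_rate))
        endo_rows.append({"sample": f"sample{s}",
                          "n_mapped_nonclonal": n_mapped,
                          "n_total": cfg.n_shotgun_reads})
    write_tsv(pd.DataFrame(endo_rows), out / "shotgun_counts.tsv")

    sex_rows = []
    for s, sex in enumerate(cfg.sample_sexes):
        s_cfg = sim.with_(seed=cfg.stage_seed("simulate", 100 + s))
        n_x, n_y = simulate_sex_counts(sex, s_cfg, n_reads=cfg.sex_n_reads,
                                       male_ry=cfg.male_ry)
        sex_rows.append({"sample": f"sample{s}", "true_sex": sex,
                         "n_x": n_x, "n_y": n_y})
    write_tsv(pd.DataFrame(sex_rows), out / "sex_counts.tsv")

    moderns, _, labels = simulate_modern_genotypes(
        n_pops=cfg.pca_n_pops, n_per_pop=cfg.pca_n_per_pop,
        fst=cfg.pca_fst, ancestral_freqs=panel.allele_frequencies(),
        seed=cfg.stage_seed("simulate", 500))
    mod = pd.DataFrame(moderns, columns=[str(p) for p in panel.positions])
    mod.insert(0, "group", labels)
    mod.insert(0, "sample", [f"mod{i}" for i in range(len(labels))])
    write_tsv(mod, out / "moderns.tsv")

    # synthetic trait panel: the four sweep rsids mapped onto panel sites
    rsids = ["rs1426654", "rs16891982", "rs2733831", "rs4988235"]
    pick = np.linspace(0, panel.n_sites - 1, len(rsids)).astype(int)
    write_tsv(pd.DataFrame({
        "rsid": rsids, "chrom": panel.chrom,
        "pos": panel.positions[pick],
        "effect_allele": panel.alt[pick],
        "gene": ["SLC24A5", "SLC45A2", "TYRP1", "MCM6/LCT"],
        "trait": ["skin pigmentation", "skin pigmentation",
                  "hair/iris pigmentation", "lactase persistence"],
    }), out / "trait_panel_synthetic.tsv")

    write_tsv(pd.DataFrame({
        "sample": [f"sample{s}" for s in range(cfg.n_samples)],
        "age_cal_bc": list(cfg.sample_ages),
        "sex": list(cfg.sample_sexes),
    }), out / "samples.tsv")


def stage_damage(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    shotgun = pd.read_csv(out / "shotgun_counts.tsv", sep="\t")
    rows, fit_rows = [], []
    for s in range(cfg.n_samples):
        reads = read_reads_tsv(out / f"damage_reads_{s}.tsv")
        sites = pd.read_csv(out / f"damage_sites_{s}.tsv", sep="\t")
        site_alleles = dict(zip(sites["pos"], sites["ref"]))
        prof = damage_profile(reads, site_alleles)
        df = prof.to_frame()
        df.insert(0, "sample", f"sample{s}")
        rows.append(df)
        fit = fit_decay(prof.ct_rate_5p)
        fit_rows.append({"sample": f"sample{s}", "end": "5p",
                         "amplitude": fit.amplitude,
                         "decay_constant": fit.decay_constant,
                         "rss": fit.rss, "flag": fit.flag})
    write_tsv(pd.concat(rows, ignore_index=True), out / "damage_profile.tsv")
    write_tsv(pd.DataFrame(fit_rows), out / "damage_fits.tsv")
    shotgun["endogenous_pct"] = [
        endogenous_fraction(r.n_mapped_nonclonal, r.n_total)
        for r in shotgun.itertuples()]
    write_tsv(shotgun, out / "endogenous_report.tsv")


def stage_sex(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    counts = pd.read_csv(out / "sex_counts.tsv", sep="\t")
    rows = []
    for r in counts.itertuples():
        call = determine_sex(int(r.n_x), int(r.n_y))
        rows.append({"sample": r.sample, "n_x": call.n_x, "n_y": call.n_y,
                     "ry": call.ry, "ci_low": call.ci_low,
                     "ci_high": call.ci_high, "call": call.call})
    write_tsv(pd.DataFrame(rows), out / "sex_report.tsv")


def stage_contam(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    sex_report = pd.read_csv(out / "sex_report.tsv", sep="\t")
    rows = []
    for s in range(cfg.n_samples):
        mt_reads = read_reads_tsv(out / f"mt_reads_{s}.tsv")
        diag = pd.read_csv(out / f"mt_diagnostics_{s}.tsv", sep="\t")
        est = mt_contamination(mt_reads, diag)
        rows.append({"sample": f"sample{s}", "method": est.method,
                     "estimate": est.estimate, "ci_low": est.ci_low,
                     "ci_high": est.ci_high,
                     "n_informative": est.n_informative})
        if sex_report.loc[s, "call"] == "XY":
            x_reads = pd.read_csv(out / f"x_reads_{s}.tsv", sep="\t")
            x_sites = pd.read_csv(out / f"x_sites_{s}.tsv", sep="\t")
            est = x_contamination(x_reads, x_sites,
                                  autosomal_error_rate=cfg.x_allele_error,
                                  seed=cfg.stage_seed("contam", s))
            rows.append({"sample": f"sample{s}", "method": est.method,
                         "estimate": est.estimate, "ci_low": est.ci_low,
                         "ci_high": est.ci_high,
                         "n_informative": est.n_informative})
    write_tsv(pd.DataFrame(rows), out / "contamination_report.tsv")


def stage_gl(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    panel = read_panel_vcf(out / "panel.vcf")
    for s in range(cfg.n_samples):
        reads = read_reads_tsv(out / f"reads_{s}.tsv")
        gl = build_gl_matrix(reads, panel, mode=cfg.mask_mode)
        write_tsv(gl.to_frame(), out / f"gl_{s}.tsv")


def _read_gl(path, panel) -> GLMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GLMatrix(chrom=str(df["chrom"].iloc[0]),
                    positions=df["pos"].to_numpy(),
                    ref=df["ref"].to_numpy(), alt=df["alt"].to_numpy(),
                    gl=df[["gl_rr", "gl_ra", "gl_aa"]].to_numpy(),
                    uncovered=df["uncovered"].to_numpy().astype(bool),
                    masked=df["masked"].to_numpy().astype(bool))


def _write_imputed_vcf(path, gl, calls, post) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gl.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GP,Number=3,Type=Float,'
                 'Description="Genotype probability">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 "SAMPLE\n")
        for j in range(gl.n_sites):
            gp = ",".join(f"{v:.4f}" for v in post.gp[j])
            fh.write(f"{gl.chrom}\t{gl.positions[j]}\t.\t{gl.ref[j]}\t"
                     f"{gl.alt[j]}\t.\tPASS\t.\tGT:GP\t"
                     f"{gt_map[int(calls.genotypes[j])]}:{gp}\n")


def stage_impute(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    panel = read_panel_vcf(out / "panel.vcf")
    for s in range(cfg.n_samples):
        gl = _read_gl(out / f"gl_{s}.tsv", panel)
        post = forward_backward(gl, panel, cfg.hmm)
        calls = call_genotypes(post, cfg.gp_threshold_genomewide)
        write_tsv(pd.DataFrame({
            "pos": post.positions, "gp_rr": post.gp[:, 0],
            "gp_ra": post.gp[:, 1], "gp_aa": post.gp[:, 2],
            "call": calls.genotypes,
        }), out / f"posterior_{s}.tsv")
        _write_imputed_vcf(out / f"imputed_{s}.vcf", gl, calls, post)


def stage_evaluate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    panel = read_panel_vcf(out / "panel.vcf")
    rows = []
    for s in range(cfg.n_samples):
        truth = pd.read_csv(out / f"truth_{s}.tsv", sep="\t")
        post = pd.read_csv(out / f"posterior_{s}.tsv", sep="\t")
        from .impute import CalledGenotypes, GenotypePosterior
        posterior = GenotypePosterior(
            positions=post["pos"].to_numpy(),
            gp=post[["gp_rr", "gp_ra", "gp_aa"]].to_numpy(), loglik=0.0)
        for t in (cfg.gp_threshold_genomewide, cfg.gp_threshold_single_locus):
            rpt = concordance(call_genotypes(posterior, t),
                              truth["genotype"].to_numpy())
            row = {"sample": f"sample{s}"}
            row.update(rpt.to_dict())
            rows.append(row)
    write_tsv(pd.DataFrame(rows), out / "concordance.tsv")

    sim = cfg.simulation.with_(seed=cfg.stage_seed("simulate"))
    s_cfg = sim.with_(seed=cfg.stage_seed("simulate", 1),
                      founder_count=cfg.sample_founder_counts[0])
    truth0 = simulate_truth(simulate_panel(sim), s_cfg)
    sweep = coverage_sweep(truth0, read_panel_vcf(out / "panel.vcf"), s_cfg,
                           coverages=cfg.eval_coverages,
                           thresholds=(cfg.gp_threshold_genomewide,),
                           params=cfg.hmm, n_reps=cfg.eval_n_reps,
                           seed=cfg.stage_seed("evaluate"),
                           mask_mode=cfg.mask_mode)
    write_tsv(sweep, out / "coverage_sweep.tsv")


def stage_pca(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    mod = pd.read_csv(out / "moderns.tsv", sep="\t")
    G = mod.drop(columns=["sample", "group"]).to_numpy(dtype=float)
    model = reference_pca(G)
    rows = [{"sample": r, "group": g, "PC1": c[0], "PC2": c[1],
             "transformed": 0}
            for r, g, c in zip(mod["sample"], mod["group"], model.coords)]
    for s in range(cfg.n_samples):
        post = pd.read_csv(out / f"posterior_{s}.tsv", sep="\t")
        dosage = post["call"].to_numpy(dtype=float)
        dosage[dosage < 0] = np.nan
        coord = cosample_project(G, dosage, model)
        rows.append({"sample": f"sample{s}", "group": "ancient",
                     "PC1": coord[0], "PC2": coord[1], "transformed": 1})
    write_tsv(pd.DataFrame(rows), out / "pca.tsv")


def stage_roh(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    seg_frames, totals = [], []
    for s in range(cfg.n_samples):
        post = pd.read_csv(out / f"posterior_{s}.tsv", sep="\t")
        segs = detect_roh(post["call"].to_numpy(), post["pos"].to_numpy(),
                          cfg.roh, chrom=cfg.simulation.chrom)
        df = segments_to_frame(segs)
        df.insert(0, "sample", f"sample{s}")
        seg_frames.append(df)
        tot = classify_and_total(segs, cfg.roh)
        tot["sample"] = f"sample{s}"
        totals.append(tot)
        bed = segments_to_bed(segs)
        bed.to_csv(out / f"roh_{s}.bed", sep="\t", index=False, header=False)
    write_tsv(pd.concat(seg_frames, ignore_index=True),
              out / "roh_segments.tsv")
    tot_df = pd.DataFrame(totals)[["sample", "short_mb", "long_mb",
                                   "total_mb"]]
    write_tsv(tot_df, out / "roh_totals.tsv")
    if cfg.n_samples >= 3:
        reg = roh_age_regression(tot_df["total_mb"].to_numpy(),
                                 np.asarray(cfg.sample_ages))
        write_tsv(pd.DataFrame([reg]), out / "roh_regression.tsv")


def stage_traits(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    panel = read_panel_vcf(out / "panel.vcf")
    traits = pd.read_csv(out / "trait_panel_synthetic.tsv", sep="\t",
                         dtype={"chrom": str})
    from .impute import GenotypePosterior
    reports = {}
    for s in range(cfg.n_samples):
        post = pd.read_csv(out / f"posterior_{s}.tsv", sep="\t")
        posterior = GenotypePosterior(
            positions=post["pos"].to_numpy(),
            gp=post[["gp_rr", "gp_ra", "gp_aa"]].to_numpy(), loglik=0.0)
        rpt = extract_trait_genotypes(posterior, panel.ref, panel.alt,
                                      traits,
                                      cfg.gp_threshold_single_locus)
        out_rpt = rpt.copy()
        out_rpt.insert(0, "sample", f"sample{s}")
        reports[f"sample{s}"] = rpt
        write_tsv(out_rpt, out / f"traits_{s}.tsv")
    ages = {f"sample{s}": cfg.sample_ages[s] for s in range(cfg.n_samples)}
    tidy = trait_trajectory(reports, ages)
    write_tsv(tidy, out / "trait_trajectory.tsv")
    write_tsv(tidy.attrs["summary"], out / "trait_summary.tsv")


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "damage": stage_damage,
    "sex": stage_sex,
    "contam": stage_contam,
    "gl": stage_gl,
    "impute": stage_impute,
    "evaluate": stage_evaluate,
    "pca": stage_pca,
    "roh": stage_roh,
    "traits": stage_traits,
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in order and write the run manifest."""
    cfg.validate()
    out = _out(cfg)
    for name, func in STAGE_FUNCS.items():
        log.info("running stage %s", name)
        try:
            func(cfg)
        except Exception as exc:  # partial outputs retained
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    manifest = {
        "package": "paleopipe",
        "version": __version__,
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "artifacts": sorted(p.name for p in out.iterdir()
                            if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
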