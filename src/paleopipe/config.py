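"""Pipeline configuration: YAML round-trip with strict key validation.

A single global seed deterministically derives per-stage seeds so any
stage can be re-run standalone with identical randomness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .impute import HMMParams
from .roh import ROHConfig
from .simulate import ConfigError, SimulationConfig

STAGES = ("simulate", "damage", "sex", "contam", "gl", "impute",
          "evaluate", "pca", "roh", "traits")


@dataclass
class PipelineConfig:
    """Full-run configuration; unknown keys are rejected at load time."""

    seed: int = 1
    outdir: str = "paleopipe_out"
    gp_threshold_genomewide: float = 0.99
    gp_threshold_single_locus: float = 0.85
    mask_mode: str = "site-flat"

    n_samples: int = 3
    sample_ages: tuple = (5700.0, 3000.0, 900.0)  # median cal BC, oldest first
    sample_sexes: tuple = ("XY", "XX", "XY")
    # founder pool per sample: a small pool emulates the restricted
    # ancestral population size expected for the oldest individual
    sample_founder_counts: tuple = (2, 10, 10)
    endogenous_rate: float = 0.6
    n_shotgun_reads: int = 100_000
    damage_coverage: float = 5.0  # depth of the invariant damage-control set
    damage_n_sites: int = 2000

    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_haplotypes=60, n_sites=1500, chrom_length=3_000_000))
    hmm: HMMParams = field(default_factory=HMMParams)
    roh: ROHConfig = field(default_factory=ROHConfig)

    sex_n_reads: int = 10_000
    male_ry: float = 0.089
    mt_n_diagnostic: int = 50
    mt_depth: float = 100.0
    x_n_sites: int = 2000
    x_depth: float = 5.0
    x_allele_error: float = 0.001

    eval_coverages: tuple = (0.5, 1.0)
    eval_n_reps: int = 2

    pca_n_pops: int = 2
    pca_n_per_pop: int = 40
    pca_fst: float = 0.05

    def validate(self) -> None:
        for name in ("gp_threshold_genomewide", "gp_threshold_single_locus"):
            t = getattr(self, name)
            if not (1 / 3 < t <= 1.0):
                raise ConfigError(f"{name}={t} outside (1/3, 1]")
        if self.mask_mode not in ("site-flat", "genotype-flat"):
            raise ConfigError(f"unknown mask_mode {self.mask_mode!r}")
        if not (len(self.sample_ages) == len(self.sample_sexes)
                == len(self.sample_founder_counts) == self.n_samples):
            raise ConfigError(
                "sample_ages/sample_sexes/sample_founder_counts must all "
                "have n_samples entries")
        for s in self.sample_sexes:
            if s not in ("XX", "XY"):
                raise ConfigError(f"bad sex {s!r}")
        self.simulation.validate()
        self.hmm.validate()
        self.roh.validate()

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic per-stage (and per-sample) seed below 2^31."""
        h = np.random.SeedSequence(
            [self.seed, STAGES.index(stage), index]).generate_state(1)[0]
        return int(h % (2 ** 31))

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        return plain(dataclasses.asdict(self))


def _build(cls, data: dict, context: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[f.name] = v
    return cls(**coerced)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    nested = {}
    for key, cls in (("simulation", SimulationConfig), ("hmm", HMMParams),
                     ("roh", ROHConfig)):
        if key in raw:
            nested[key] = _build(cls, raw.pop(key) or {}, key)
    cfg = _build(PipelineConfig, raw, "pipeline config")
    for key, val in nested.items():
        cfg = dataclasses.replace(cfg, **{key: val})
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
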