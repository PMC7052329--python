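"""Benchmark run configuration with deterministic seed derivation.

All randomness in a benchmark run flows from ``master_seed``: stage seeds
are derived through :class:`numpy.random.SeedSequence` so a configuration
file plus one integer reproduces the whole run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .containers import ParameterError

DEFAULT_MODELS = ["ANOVA", "GLM", "MLM", "CMLM", "ECMLM", "SUPER", "MLMM", "FarmCPU"]
DEFAULT_CORRECTIONS = ["bonferroni", "fdr_bh", "pfdr_storey"]


@dataclass
class SimulatorParams:
    """Genotype-simulator settings (see :func:`gwasbench.simulate.simulate_genotypes`)."""

    n_individuals: int = 300
    n_markers: int = 5000
    n_chromosomes: int = 10
    n_subpops: int = 2
    fst: float = 0.1
    family_size: int = 5
    block_len_bp: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    marker_spacing_bp: int = 10_000
    haplotype_pool: int = 8


@dataclass
class TraitScenario:
    """One simulated-trait condition: heritability H, QTL count Q, reps r."""

    h2: float
    n_qtl: int
    n_reps: int = 1
    seed: int | None = None
    name: str | None = None


@dataclass
class RunConfig:
    genotype_source: str = "simulate"  # "simulate" or a file path
    genotype_format: str = "hapmap"
    simulator: SimulatorParams = field(default_factory=SimulatorParams)
    scenarios: list[TraitScenario] = field(
        default_factory=lambda: [TraitScenario(h2=0.6, n_qtl=20)]
    )
    effect_dist: str = "normal"
    n_pcs: int = 3
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    model_options: dict = field(default_factory=dict)
    corrections: list[str] = field(default_factory=lambda: list(DEFAULT_CORRECTIONS))
    logp_cut: float = 3.5
    alpha: float = 0.05
    match_rule: str = "exact"
    ld_match_r2: float = 0.5
    ld_match_window_bp: int = 1_000_000
    qc_maf_min: float = 0.05
    qc_miss_max: float = 0.10
    output_dir: str = "gwasbench_out"
    master_seed: int = 0
    log_level: str = "INFO"

    # -- seeds ----------------------------------------------------------
    def stage_seed(self, stage: int) -> int:
        """Deterministic 31-bit seed for a numbered pipeline stage."""
        ss = np.random.SeedSequence([int(self.master_seed), int(stage)])
        return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)

    # -- construction ---------------------------------------------------
    def build_genotypes(self):
        from .simulate import simulate_genotypes

        if self.genotype_source != "simulate":
            from .io import read_genotypes

            return read_genotypes(self.genotype_source, self.genotype_format)
        p = self.simulator
        return simulate_genotypes(
            p.n_individuals, p.n_markers, p.n_chromosomes, p.n_subpops, p.fst,
            p.family_size, p.block_len_bp, tuple(p.maf_range), p.missing_rate,
            seed=self.stage_seed(0), marker_spacing_bp=p.marker_spacing_bp,
            haplotype_pool=p.haplotype_pool,
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulator"]["maf_range"] = list(d["simulator"]["maf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulator", {})
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        scen = [TraitScenario(**s) for s in d.pop("scenarios", [])]
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulator=SimulatorParams(**sim), scenarios=scen, **d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
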