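"""Pipeline configuration: every threshold in one validated mapping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # inputs
    alignment: str | None = None
    reference: str | None = None
    genes_gtf: str | None = None
    repeat_bed: str | None = None
    editing_db: str | None = None
    population_vcfs: list[str] = field(default_factory=list)
    matched_dna_vcf: str | None = None
    region: str | None = None
    sample_id: str = "sample"
    seed: int = 0

    # read QC / pileup
    min_mapq: int = 20
    single_end: bool = False
    min_depth: int = 10
    count_n_in_depth: bool = False
    near_end_bp: int = 6
    near_junction_bp: int = 5

    # genotyper
    p_m: float = 1e-7
    default_p_alt: float = 1e-4
    quadrature_points: int = 512
    min_candidate_posterior: float = 0.05
    multiallelic_max_second_vaf: float = 0.02

    # empirical filters
    min_vaf: float = 0.05
    min_alt_reads: int = 5
    homopolymer_min_run: int = 5
    homopolymer_pad: int = 1
    bias_alpha: float = 0.01
    linkage_min_shared: int = 2
    linkage_window_bp: int = 1000
    realign_match: float = 1.0
    realign_mismatch: float = -2.0
    realign_gap_open: float = -4.0
    realign_gap_extend: float = -1.0
    realign_min_margin: float = 5.0

    hq_min_fraction: float = 0.5

    # editing / strand filters
    editing_mode: str = "default"  # default | full_ag_tc
    flag_only: bool = False
    oxo_g_mode: bool = False

    # germline / cohort
    max_vaf: float = 0.5
    dna_vaf_somatic_max: float = 0.02
    max_individuals: int = 1

    def validate(self) -> "PipelineConfig":
        probs = {
            "min_candidate_posterior": self.min_candidate_posterior,
            "min_vaf": self.min_vaf,
            "bias_alpha": self.bias_alpha,
            "hq_min_fraction": self.hq_min_fraction,
            "max_vaf": self.max_vaf,
            "dna_vaf_somatic_max": self.dna_vaf_somatic_max,
            "p_m": self.p_m,
            "default_p_alt": self.default_p_alt,
            "multiallelic_max_second_vaf": self.multiallelic_max_second_vaf,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"config key {name}={value} outside [0, 1]")
        for name in (
            "min_mapq",
            "min_depth",
            "near_end_bp",
            "near_junction_bp",
            "min_alt_reads",
            "homopolymer_min_run",
            "homopolymer_pad",
            "linkage_min_shared",
            "max_individuals",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"config key {name} must be non-negative")
        if self.quadrature_points < 64:
            raise ValueError("config key quadrature_points must be >= 64")
        if self.editing_mode not in ("default", "full_ag_tc"):
            raise ValueError(
                f"config key editing_mode={self.editing_mode!r} not one of "
                "'default', 'full_ag_tc'"
            )
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Defaults merged with a YAML file and explicit overrides.

    Unknown keys are rejected by name; every value is range-validated.
    """
    data: dict = {}
    if path is not None:
        with open(path) as handle:
            loaded = yaml.safe_load(handle)
        if loaded:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**data).validate()
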