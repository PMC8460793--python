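"""Run configuration: input paths and thresholds, YAML-loadable.

A flat key space mirrors the CLI flags; unknown keys are rejected so a
typo in a config file fails loudly rather than silently using a
default.  CLI flags win over config-file values on conflict.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml


@dataclass
class RunConfig:
    # inputs
    trio_vcf: Optional[str] = None
    proband_smap: Optional[str] = None
    mother_smap: Optional[str] = None
    father_smap: Optional[str] = None
    tenx_large_svs: Optional[str] = None
    tenx_dels: Optional[str] = None
    panel: Optional[str] = None
    cohort: Optional[str] = None
    syndromes: Optional[str] = None
    exons: Optional[str] = None
    genes: Optional[str] = None
    ontology: Optional[str] = None
    annotations: Optional[str] = None
    phenome: Optional[str] = None
    # outputs
    out: Optional[str] = None
    summary_json: Optional[str] = None
    # trio sample names in the VCF
    proband_sample: str = "PROBAND"
    mother_sample: Optional[str] = "MOTHER"
    father_sample: Optional[str] = "FATHER"
    # thresholds
    gq_min: int = 20
    dp_min: int = 10
    require_pass: bool = True
    af_max: float = 0.05
    confidence_min: float = 0.5
    reciprocal_fraction: float = 0.5
    bionano_interval_bp: int = 20_000
    tenx_interval_bp: int = 10_000
    max_cohort_occurrences: int = 2
    # case metadata
    proband_sex: str = "unknown"
    seed: int = 0
    genome_build: str = "GRCh38"

    def __post_init__(self) -> None:
        if not (0 <= self.af_max <= 1):
            raise ValueError("af_max must be in [0, 1]")
        if not (0 < self.reciprocal_fraction <= 1):
            raise ValueError("reciprocal_fraction must be in (0, 1]")
        if not (0 <= self.confidence_min <= 1):
            raise ValueError("confidence_min must be in [0, 1]")
        if self.bionano_interval_bp <= 0 or self.tenx_interval_bp <= 0:
            raise ValueError("breakpoint interval widths must be positive")
        if self.gq_min < 0 or self.dp_min < 0 or self.max_cohort_occurrences < 0:
            raise ValueError("thresholds must be >= 0")
        if self.proband_sex not in ("male", "female", "unknown"):
            raise ValueError("proband_sex must be male/female/unknown")

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(doc) - cls.field_names()
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def merged(self, **overrides) -> "RunConfig":
        """A copy with non-None overrides applied (flags beat config)."""
        unknown = set(overrides) - self.field_names()
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        values = dataclasses.asdict(self)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**values)
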