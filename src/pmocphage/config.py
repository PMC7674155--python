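"""Declarative pipeline configuration.

Every analysis threshold is a named key with the published value as its
default, so any deviation is visible in configs and logs. Coordinates are
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import CommunityConfig


@dataclass
class PipelineConfig:
    # detection
    min_breadth: float = 0.75
    phage_min_identity: float = 0.95
    host_min_identity: float = 0.98
    marker_min_breadth: float = 0.5
    # host assignment
    host_assign_min_identity: float = 90.0  # percent
    # CRISPR
    spacer_min_match: int = 30
    crispr_min_spacer: int = 17
    # protein families
    family_min_genomes: int = 5
    mcl_inflation: float = 2.0
    # variants
    q_cutoff: float = 0.05
    # growth index
    growth_min_coverage: float = 5.0
    # screen
    pmoc_report_threshold: float = 50.0  # percent identity
    # expression / activity policy
    activity_min_fraction: float = 0.01
    activity_min_reads: int = 50
    transcriptome_reads: int = 30_000
    # variants simulation scale
    snp_sites: int = 300
    snp_shifted_fraction: float = 0.1
    snp_effect: float = 0.5
    snp_depth: int = 200

    seed: int = 0
    community: CommunityConfig = field(default_factory=CommunityConfig)

    def __post_init__(self) -> None:
        if isinstance(self.community, dict):
            community = dict(self.community)
            if "genome_length_range" in community:
                community["genome_length_range"] = tuple(
                    community["genome_length_range"]
                )
            if "read_identity_mix" in community:
                community["read_identity_mix"] = tuple(
                    tuple(pair) for pair in community["read_identity_mix"]
                )
            self.community = CommunityConfig(**community)

    def validate(self) -> None:
        for name in ("min_breadth", "marker_min_breadth", "q_cutoff",
                     "activity_min_fraction", "snp_shifted_fraction", "snp_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("phage_min_identity", "host_min_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} is a fraction in [0, 1], got {v}")
        if not 0.0 <= self.host_assign_min_identity <= 100.0:
            raise ValueError("host_assign_min_identity is a percentage")
        if self.mcl_inflation <= 1.0:
            raise ValueError("mcl_inflation must exceed 1")
        for name in ("spacer_min_match", "crispr_min_spacer", "family_min_genomes",
                     "activity_min_reads", "transcriptome_reads", "snp_sites",
                     "snp_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.community.validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
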