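"""Pipeline configuration: one YAML file, validated at load.

Unknown keys are rejected and every numeric parameter is range-checked, so a
typo in a config file fails loudly instead of silently running with a
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, Optional

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # paths
    genome_fasta: Optional[str] = None
    genes_bed: Optional[str] = None
    coding_bed: Optional[str] = None
    chrom_sizes: Optional[str] = None
    #: condition -> {"plus": path, "minus": path}
    coverage: Dict[str, Dict[str, str]] = field(default_factory=dict)
    outdir: str = "polterm_out"
    # parameters
    min_tract_len: int = 4
    max_search_bp: int = 1000
    secondary_window: int = 700
    rt_span: int = 1000
    window: int = 20
    step: int = 19
    quantile: float = 0.95
    max_gap: int = 20
    pseudocount: float = 1.0
    body_bins: int = 100
    flank: int = 500
    dependency_window: int = 700
    spacer_cutoff: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("min_tract_len", self.min_tract_len >= 1),
            ("max_search_bp", self.max_search_bp >= 1),
            ("secondary_window", self.secondary_window >= 1),
            ("rt_span", self.rt_span >= 1),
            ("window", self.window >= 1),
            ("step", 1 <= self.step),
            ("quantile", 0.0 < self.quantile < 1.0),
            ("max_gap", self.max_gap >= 0),
            ("pseudocount", self.pseudocount >= 0),
            ("body_bins", self.body_bins >= 1),
            ("flank", self.flank >= 0),
            ("dependency_window", self.dependency_window >= 1),
            ("spacer_cutoff", self.spacer_cutoff >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"parameter {name}={getattr(self, name)!r} "
                                  "out of range")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"{path}: unknown config keys: {', '.join(sorted(unknown))}"
            )
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
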