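"""Pipeline-wide configuration with the method's stated defaults.

Stated constants: domain-hit inclusion threshold 0.01 (strictly below),
MCL inflation 5, at most two intervening genes between cognate partners.
The remainder (alignment scoring, E-value cutoff, operon gap threshold)
are declared, configurable defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of every pipeline stage, in one flat record."""

    # domain extraction
    inclusion_threshold: float = 0.01
    # pairwise similarity
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    evalue_cutoff: float = 10.0
    # graph + MCL
    weight_cap: float = 200.0
    inflation: float = 5.0
    expansion: int = 2
    prune_below: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-8
    # genome context
    max_gap_bp: int = 200
    max_intervening: int = 2
    # interaction model
    count_mode: str = "per_instance_pair"
    top_k: int = 1
    probability_floor: float = 0.0
    # simulation / anything stochastic
    seed: int = 0

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - cls.field_names()
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        """Echo the effective configuration beside the outputs."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def replace(self, **kwargs) -> "PipelineConfig":
        unknown = set(kwargs) - self.field_names()
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **kwargs)
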