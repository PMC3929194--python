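"""Pipeline configuration: validated parameters for every stage.

Defaults mirror the published analysis: hard threshold tau = 0.7, soft
power beta = 7, dendrogram height cutoff 0.99, and 6 + 5 hub/bottleneck
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    expression: str
    out_dir: str
    probe_map: str | None = None
    traits: str | None = None
    gene_sets: str | None = None
    quantile_normalize: bool = True
    min_probes: int = 2
    tau: float = 0.7
    beta: float = 7.0
    height_cutoff: float = 0.99
    min_module_size: int = 20
    n_top_degree: int = 6
    n_top_bc: int = 5
    bc_network_mode: str = "binary"
    edge_length: str = "reciprocal"
    enrichment_method: str = "fisher"
    multiple_testing: str = "fdr_bh"
    edge_cutoff: float = 0.02
    candidate_covariates: tuple[str, ...] = ("age", "housekeeping")
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must lie in (0, 1], got {self.tau}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0 < self.height_cutoff <= 1:
            raise ValueError(
                f"height_cutoff must lie in (0, 1], got {self.height_cutoff}"
            )
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.n_top_degree < 0 or self.n_top_bc < 0:
            raise ValueError("candidate counts must be non-negative")
        if self.bc_network_mode not in ("binary", "weighted"):
            raise ValueError("bc_network_mode must be 'binary' or 'weighted'")
        if self.edge_length not in ("reciprocal", "one_minus"):
            raise ValueError("edge_length must be 'reciprocal' or 'one_minus'")
        if self.enrichment_method not in ("fisher", "ease"):
            raise ValueError("enrichment_method must be 'fisher' or 'ease'")
        if not 0 <= self.edge_cutoff <= 1:
            raise ValueError("edge_cutoff must lie in [0, 1]")
        unknown = set(self.candidate_covariates) - {"age", "housekeeping"}
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "candidate_covariates" in data:
            data = dict(data)
            data["candidate_covariates"] = tuple(data["candidate_covariates"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)
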