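"""Pipeline configuration: thresholds, seed and file paths."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .io import ConfigurationError


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full pipeline run.

    fc_cutoff: linear fold-change threshold (the ">= +/-2.0" convention);
    alpha_fdr: Benjamini-Hochberg FDR level for differential expression;
    alpha_fwer: Bonferroni family-wise level for the interaction screen;
    min_total_count: low-count filter applied in miRNA mode;
    pseudocount: offset added to CPM before taking log2.
    """

    counts_path: str | None = None
    design_path: str | None = None
    out_dir: str = "results"
    fc_cutoff: float = 2.0
    alpha_fdr: float = 0.05
    alpha_fwer: float = 0.05
    min_total_count: int = 10
    pseudocount: float = 1.0
    mirna: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_cutoff < 1:
            raise ConfigurationError("fc_cutoff must be >= 1")
        for name in ("alpha_fdr", "alpha_fwer", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.min_total_count < 0:
            raise ConfigurationError("min_total_count must be nonnegative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML or JSON (decided by extension, YAML parses both)."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
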