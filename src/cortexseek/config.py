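"""Pipeline configuration.

One flat config object carries every threshold the analysis uses:

r_threshold
    Minimum Pearson correlation (strict ``>``) for an edge in the spatial
    co-expression network.  Default 0.7.
fold_min
    Minimum linear fold change for the differential screens and the
    zone-enrichment prefilter.  Default 6.
alpha
    Family-wise significance level applied to Holm-adjusted p-values.
    Default 1e-9.
k_extend
    Number of associated genes added when a query list is extended over the
    association-network compendium.  Default 50.
propagation_alpha
    Restart/diffusion parameter of the label-propagation scorer.  Default 0.85.
seed
    Seed for every stochastic stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    r_threshold: float = 0.7
    fold_min: float = 6.0
    alpha: float = 1e-9
    k_extend: int = 50
    propagation_alpha: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold <= 1.0:
            raise ValueError("r_threshold must lie in (0, 1]")
        if self.fold_min < 1.0:
            raise ValueError("fold_min must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k_extend < 0:
            raise ValueError("k_extend must be non-negative")
        if not 0.0 < self.propagation_alpha < 1.0:
            raise ValueError("propagation_alpha must lie in (0, 1)")
        self.k_extend = int(self.k_extend)
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
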