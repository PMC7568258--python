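"""Pipeline configuration: every analysis threshold in one place.

Defaults are the published constants: the 0.5 % abundance filter, the 0.1 %
floor for log/ratio computations, the fold-1.2 / FDR-0.05 differential-
abundance call, the cured (<= 1) / sick (>= 5) score extremes, the 0.3
moderate-correlation threshold, and the < 2-fold / p > 0.09 core-microbiota
rule.  Serialization round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    # abundance filtering
    min_percent: float = 0.5        # OTU filter: > this % in >= min_samples samples
    min_samples: int = 1
    floor: float = 0.1              # % floor inside log/ratio computations
    # differential abundance
    fc_min: float = 1.2             # fold-change call threshold
    fdr_max: float = 0.05           # BH FDR call threshold
    # core microbiota
    core_fold_max: float = 2.0
    core_p_min: float = 0.09
    core_min_mean: float = 0.2      # % mean required in both groups
    # triage
    cured_max: float = 1.0          # overall score ceiling for "cured"
    sick_min: float = 5.0           # overall score floor for "sick"
    corr_threshold: float = 0.3     # moderate harmonized-correlation threshold
    cs_alpha: float = 0.05          # pairwise-test alpha in the extreme screen
    multiplicity_method: str = "bonferroni"
    multiplicity_family: str = "candidates"
    # ordination
    jaccard_mode: str = "quantitative"
    presence_threshold: float = 0.5
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "min_percent", "floor", "fc_min", "fdr_max", "core_fold_max",
            "core_p_min", "core_min_mean", "cured_max", "sick_min",
            "corr_threshold", "cs_alpha", "presence_threshold",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be at least 1")
        if self.cured_max >= self.sick_min:
            raise ValueError("cured_max must be below sick_min")
        if self.jaccard_mode not in ("quantitative", "binary"):
            raise ValueError(f"unknown jaccard_mode {self.jaccard_mode!r}")
        if self.multiplicity_method not in ("bonferroni", "holm", "fdr_bh"):
            raise ValueError(f"unknown multiplicity_method {self.multiplicity_method!r}")

    def to_yaml(self, path: Path | str | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Path | str) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping of option: value")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
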