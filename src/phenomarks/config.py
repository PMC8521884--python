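"""Run configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import CohortConfig


@dataclass
class RunConfig:
    """Serializable configuration of one end-to-end run."""

    seed: int = 0
    output_dir: str = "phenomarks_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    min_confidence: float = 0.70
    sphericity_alpha: float = 0.05
    alpha: float = 0.05
    fdr_family: str = "condition"  # or "table"
    neutral_band: float = 0.5
    outer_threshold: float = 1.5
    min_speech_s: float = 10.0
    log_level: str = "INFO"

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if self.cohort.seed is None:
            self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
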