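"""Pipeline configuration with strict key validation.

Defaults equal the primary analysis choices: Abraham ECV, the printed PEW
thresholds, the standard CIS fatigue-severity item map, plain (non-Firth)
logistic fits and the full sensitivity grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .nutrition import CIS_FATIGUE_ITEMS, CIS_REVERSE_ITEMS, PewThresholds

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    ecv_formula: str = "abraham"
    thresholds: dict = field(
        default_factory=lambda: asdict(PewThresholds())
    )
    cis_item_map: tuple = CIS_FATIGUE_ITEMS
    cis_reverse_items: tuple = CIS_REVERSE_ITEMS
    n_patients: int = 59
    seed: int = 42
    sensitivity: bool = True
    firth: bool = False
    output_dir: str = "results"
    simulator: dict = field(default_factory=dict)  # forwarded to generate_cohort

    def __post_init__(self) -> None:
        if self.ecv_formula not in ("abraham", "bird"):
            raise ConfigError(f"ecv_formula must be 'abraham' or 'bird', got {self.ecv_formula!r}")
        known = set(asdict(PewThresholds()))
        unknown = set(self.thresholds) - known
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        self.thresholds = {**asdict(PewThresholds()), **self.thresholds}
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        self.cis_item_map = tuple(self.cis_item_map)
        self.cis_reverse_items = tuple(self.cis_reverse_items)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(d)

    def pew_thresholds(self) -> PewThresholds:
        return PewThresholds(**self.thresholds)

    def to_dict(self) -> dict:
        return asdict(self)
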