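"""Screening configuration with YAML round-trip.

Defaults reproduce the reference configuration: 250 Hz sampling, 30-second
segments, 10 groups, empirical Chauvenet coefficient.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["ScreenConfig"]


@dataclass
class ScreenConfig:
    sampling_rate: float = 250.0
    segment_seconds: float = 30.0
    group_count: int = 10
    method: str = "empirical"
    input_format: str = "csv"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
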