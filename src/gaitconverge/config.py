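"""Pipeline configuration with the published defaults."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .walking import Thresholds


@dataclass
class PipelineConfig:
    """All tunable pipeline settings.

    Defaults equal the published values where one exists: detection
    thresholds theta1 = 8 m/s^2, theta2 = 4 m/s^2, theta3 = 0.7 (walkers) /
    0.25 (wheelchair users) (m/s^2)^2 on 1-s windows; stride-duration
    bounds [0.25, 3] s; CP cut-off t_max = 3650 days.
    """

    theta1: float = 8.0
    theta2: float = 4.0
    theta3_walker: float = 0.7
    theta3_wheelchair: float = 0.25
    window_s: float = 1.0
    sampling_rate: float = 50.0
    median_kernel: int = 5
    ac_threshold: float = 0.3
    min_strides: int = 5
    min_peak_separation: float = 0.25
    peak_amp_quantile: float = 0.95
    peak_amp_fraction: float = 0.3
    stride_min_s: float = 0.25
    stride_max_s: float = 3.0
    exclude_physio: bool = True
    exclude_labels: tuple[str, ...] = ("physiotherapy_walk",)
    t_max: float = 3650.0
    seed: int = 0

    def thresholds(self) -> Thresholds:
        return Thresholds(theta1=self.theta1, theta2=self.theta2,
                          theta3_walker=self.theta3_walker,
                          theta3_wheelchair=self.theta3_wheelchair)

    def updated(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_labels" in data:
            data["exclude_labels"] = tuple(data["exclude_labels"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["exclude_labels"] = list(data["exclude_labels"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
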