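"""Serializable global configuration bundling every tunable stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .detector import PipelineConfig, ThresholdConfig
from .kinematics import IntegrationConfig
from .orientation import OrientationConfig
from .preprocessing import FilterConfig


@dataclass
class GlobalConfig:
    """Defaults reproduce the published pipeline constants.

    5 Hz 2nd-order low-pass; complementary-filter gains Kp=1.0, Ki=0.1
    with a 0.5 g accelerometer gate; integration gate 0.24 g, attenuation
    0.9, correction 1.2; detector thresholds 40 deg / 1.8 m/s / 5 m/s.
    """

    filter: FilterConfig = field(default_factory=FilterConfig)
    orientation: OrientationConfig = field(default_factory=OrientationConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(
            filter=self.filter,
            orientation=self.orientation,
            integration=self.integration,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GlobalConfig":
        return cls(
            filter=FilterConfig(**d.get("filter", {})),
            orientation=OrientationConfig(**d.get("orientation", {})),
            integration=IntegrationConfig(**d.get("integration", {})),
            thresholds=ThresholdConfig(**d.get("thresholds", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GlobalConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
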