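"""Run configuration for the pipeline driver."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

ALL_STAGES = ("simulate", "thermo", "qha", "consensus", "expansion", "packing")


@dataclass
class RunConfig:
    """Validated configuration: temperature grid (K), reference pressure
    (Pa), reference temperatures (K), master seed, per-stage blocks."""

    t_start_k: float = 10.0
    t_stop_k: float = 500.0
    t_step_k: float = 2.0
    pressure_pa: float = 101325.0
    tref_k: float = 423.15
    report_t_k: float = 298.15
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    stage_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_step_k <= 0:
            raise ValueError("temperature step must be positive")
        if not self.t_start_k < self.t_stop_k:
            raise ValueError("temperature grid start must precede stop")
        if self.t_start_k <= 0:
            raise ValueError("temperature grid must be positive (Kelvin)")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d
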