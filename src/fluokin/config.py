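"""Run configuration: one validated record drives the whole pipeline.

A :class:`RunConfig` gathers every tunable of the simulate → features →
scores → cutoffs chain.  Configs load from YAML with a versioned schema and
*strict* key checking (an unknown key is an error — silent typos in
scientific parameters are worse than a crash), and every run serializes its
config verbatim into the output metadata so any figure can be reproduced.

All randomness flows from a single master seed through named per-stage
substreams (see :func:`fluokin.synthetic_data.derive_seeds`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .kinematics import EXTREME_JERK_THRESHOLD
from .scoring import WEIGHT_GRID_STEP, Z_MULTIPLIER
from .synthetic_data import TrialConfig

SCHEMA_VERSION = 1

logger = logging.getLogger("fluokin")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class RunConfig:
    """Full parameter set of one end-to-end run."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    n_exercises: int = 40
    trial: TrialConfig = field(default_factory=TrialConfig)
    intensity_range: tuple[float, float] = (1.0, 3.5)
    smoothing_window: int = 7
    smoothing_polyorder: int = 3
    jerk_threshold: float = EXTREME_JERK_THRESHOLD
    weight_grid_step: float = WEIGHT_GRID_STEP
    normalize_dm: bool = True
    pca_method: str = "correlation"
    z_multiplier: float = Z_MULTIPLIER
    density_bin_mm: float = 10.0
    sbr_bin_width: float = 0.1
    breakpoint_grid_step: float = 0.01
    out_dir: str = "fluokin_out"

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema version {self.schema_version} not supported "
                f"(expected {SCHEMA_VERSION})"
            )
        if self.n_exercises < 1:
            raise ValueError("n_exercises must be >= 1")
        if self.smoothing_window % 2 == 0 or self.smoothing_window <= self.smoothing_polyorder:
            raise ValueError("smoothing_window must be odd and exceed the polyorder")
        if self.jerk_threshold <= 0 or self.weight_grid_step <= 0:
            raise ValueError("thresholds and grid steps must be positive")
        if not 0 < self.weight_grid_step <= 1:
            raise ValueError("weight_grid_step must lie in (0, 1]")
        lo, hi = self.intensity_range
        if not 0 < lo < hi:
            raise ValueError("intensity_range must be positive with low < high")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intensity_range"] = list(self.intensity_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "trial" in data and isinstance(data["trial"], dict):
            trial_known = {f.name for f in fields(TrialConfig)}
            trial_unknown = set(data["trial"]) - trial_known
            if trial_unknown:
                raise ValueError(f"unknown trial config keys: {sorted(trial_unknown)}")
            data["trial"] = TrialConfig(**data["trial"])
        if "intensity_range" in data:
            data["intensity_range"] = tuple(data["intensity_range"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
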