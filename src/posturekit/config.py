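"""Run configuration shared across the toolkit.

A :class:`RunConfig` gathers every tunable the modules expose — load
threshold, optional low-pass filter, centering origin, trial-count caps,
ellipse variant, velocity convention, game dynamics constants — in one
validated object. Unknown keys are rejected rather than silently ignored,
and a stable hash of the effective configuration is stamped into outputs
so any result can be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError


@dataclass
class FilterConfig:
    """Optional zero-phase Butterworth low-pass applied to COP trajectories."""

    enabled: bool = False
    cutoff_hz: float = 10.0
    order: int = 4


@dataclass
class OriginConfig:
    """How a trajectory is centered before range metrics.

    ``initial_window`` subtracts the mean COP of the first ``window_s``
    seconds (the quiet hold before an excursion); trajectories shorter
    than twice the window fall back to the whole-trial mean.
    """

    method: str = "initial_window"  # "initial_window" | "mean"
    window_s: float = 1.0


@dataclass
class EllipseConfig:
    """Sway-area ellipse variant: large-sample chi-square quantile by
    default, small-sample F-based prediction ellipse as an option."""

    method: str = "chi2"  # "chi2" | "f"
    level: float = 0.95


@dataclass
class VelocityConfig:
    """Whether "mean velocity" means planar path/duration (primary) or the
    sum of the two axis velocities (reported by some platforms)."""

    mode: str = "planar"  # "planar" | "axis_sum"


@dataclass
class MVEConfig:
    """Trial bookkeeping for the excursion protocol: three consecutive
    trials tested twice per direction gives the default cap of six."""

    max_trials_per_direction: int = 6


@dataclass
class GameConfig:
    """Constants of the headless racer surrogate (SI units)."""

    a_fwd: float = 2.0          # forward-lean acceleration gain, m/s^2
    a_brake: float = 4.0        # backward-lean braking gain, m/s^2
    speed_max: float = 15.0     # m/s
    k_steer: float = 0.5        # lateral gain, (m lateral)/(m advanced) per unit u
    capture_radius: float = 1.0  # m, herring pickup distance
    step_hz: float = 100.0      # fixed simulation rate, matches the plate
    deadzone_fraction: float = 0.1
    deadzone_mode: str = "radial_rescale"  # or "hard_zero"
    stuck_speed: float = 0.01   # m/s, below this the racer counts as stuck
    stuck_time_s: float = 5.0   # s of stuckness before an auto-reset


@dataclass
class StatsConfig:
    alpha: float = 0.05
    t_variant: str = "student"  # "student" (pooled) | "welch"
    holm: bool = False          # per-parameter raw p by default


@dataclass
class RunConfig:
    """Top-level configuration. Flat keys plus nested sections."""

    min_total_force_n: float = 50.0
    filter: FilterConfig = field(default_factory=FilterConfig)
    origin: OriginConfig = field(default_factory=OriginConfig)
    ellipse: EllipseConfig = field(default_factory=EllipseConfig)
    velocity: VelocityConfig = field(default_factory=VelocityConfig)
    mve: MVEConfig = field(default_factory=MVEConfig)
    game: GameConfig = field(default_factory=GameConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_total_force_n < 0:
            raise ConfigError("min_total_force_n must be >= 0")
        if self.origin.method not in ("initial_window", "mean"):
            raise ConfigError(f"unknown origin method: {self.origin.method!r}")
        if self.ellipse.method not in ("chi2", "f"):
            raise ConfigError(f"unknown ellipse method: {self.ellipse.method!r}")
        if not 0.0 < self.ellipse.level < 1.0:
            raise ConfigError("ellipse level must be in (0, 1)")
        if self.velocity.mode not in ("planar", "axis_sum"):
            raise ConfigError(f"unknown velocity mode: {self.velocity.mode!r}")
        if self.game.deadzone_mode not in ("radial_rescale", "hard_zero"):
            raise ConfigError(f"unknown deadzone mode: {self.game.deadzone_mode!r}")
        if self.stats.t_variant not in ("student", "welch"):
            raise ConfigError(f"unknown t variant: {self.stats.t_variant!r}")

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        """Build a config from a nested mapping, rejecting unknown keys."""
        return cls(**_coerce_fields(cls, data, path="config"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: config file must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def _coerce_fields(cls: type, data: Mapping[str, Any], path: str) -> dict:
    """Recursively map a dict onto dataclass fields, erroring on unknowns."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    out: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"{path}: unknown key {key!r}")
        sub = _SECTION_TYPES.get((cls.__name__, key))
        if sub is not None:
            if not isinstance(value, Mapping):
                raise ConfigError(f"{path}.{key}: expected a mapping")
            out[key] = sub(**_coerce_fields(sub, value, f"{path}.{key}"))
        else:
            out[key] = value
    return out


_SECTION_TYPES = {
    ("RunConfig", "filter"): FilterConfig,
    ("RunConfig", "origin"): OriginConfig,
    ("RunConfig", "ellipse"): EllipseConfig,
    ("RunConfig", "velocity"): VelocityConfig,
    ("RunConfig", "mve"): MVEConfig,
    ("RunConfig", "game"): GameConfig,
    ("RunConfig", "stats"): StatsConfig,
}


DEFAULT_CONFIG = RunConfig()
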