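"""Headless model of the COP-driven racing game.

During training the subject's COP steers a penguin racer: forward lean
adds speed, backward lean brakes, lateral lean steers, and the goal is to
collect herrings scattered along a course of varying terrain within a
time limit. This module reproduces that control loop without graphics so
training dosage and elicited postural behaviour are computable and
replayable.

The COP-to-joystick mapping is individualized: each direction is
normalized by the subject's own maximal voluntary excursion in that
direction, so equal game demand maps to equal relative postural
challenge. A deadzone around the stance origin suppresses resting sway;
by default the mapping rescales radially outside the deadzone
(magnitude ``(r - dz) / (limit - dz)``) so it stays continuous across the
deadzone boundary.

Dynamics, fixed-step at the plate's 100 Hz:

    speed' = clamp(speed + (a_fwd max(v,0) + a_brake min(v,0) - drag speed) dt, 0, v_max)
    lateral' = clamp(lateral + k_steer u speed dt, course bounds)
    position' = position + speed dt

Held forward lean therefore converges to the drag-limited terminal speed
``a_fwd v / drag``. Replays are deterministic: the same COP stream,
calibration and course give bit-identical performance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, GameConfig, RunConfig
from .cop import COPTrajectory
from .errors import CalibrationError, ContractError, ParameterError, StateError
from .protocol import MVESession, directional_limits

OCTANTS = ("R", "A-R", "A", "A-L", "L", "P-L", "P", "P-R")


# ---------------------------------------------------------------------------
# Calibration and joystick mapping
# ---------------------------------------------------------------------------

class JoystickState(NamedTuple):
    """Dimensionless control state: u lateral (+right), v fore-aft
    (+forward), each in [-1, 1]."""

    u: float
    v: float


@dataclass(frozen=True)
class Calibration:
    """Per-direction stability limits (mm) and deadzone radius (mm)."""

    limit_R: float
    limit_L: float
    limit_A: float
    limit_P: float
    deadzone_radius: float = 0.0

    def __post_init__(self) -> None:
        limits = (self.limit_R, self.limit_L, self.limit_A, self.limit_P)
        if min(limits) <= 0:
            raise CalibrationError("all stability limits must be positive")
        if not 0 <= self.deadzone_radius < min(limits):
            raise CalibrationError(
                "deadzone radius must be >= 0 and smaller than every limit"
            )

    @property
    def limits(self) -> dict[str, float]:
        return {
            "R": self.limit_R,
            "L": self.limit_L,
            "A": self.limit_A,
            "P": self.limit_P,
        }


def calibrate(session: MVESession, deadzone_fraction: float = 0.1) -> Calibration:
    """Build a calibration from a subject's assessed stability limits.

    Limits are the per-direction aggregated maximal excursions of the
    session; the deadzone is ``deadzone_fraction`` of the smallest limit.
    """
    if not 0 <= deadzone_fraction < 1:
        raise ParameterError("deadzone_fraction must be in [0, 1)")
    limits = directional_limits(session)
    for d in ("R", "L", "A", "P"):
        if d not in limits:
            raise CalibrationError(
                f"session has no trials exercising direction {d}; "
                "cannot calibrate"
            )
        if limits[d] <= 0:
            raise CalibrationError(f"zero stability limit toward {d}")
    dz = deadzone_fraction * min(limits.values())
    return Calibration(
        limit_R=limits["R"],
        limit_L=limits["L"],
        limit_A=limits["A"],
        limit_P=limits["P"],
        deadzone_radius=dz,
    )


def cop_to_joystick(
    cop_mm: Sequence[float],
    cal: Calibration,
    deadzone_mode: str = "radial_rescale",
) -> JoystickState:
    """Map a centered COP sample (mm) to joystick state.

    Each component is normalized by the limit of the direction it points
    to; the effective radial limit along the COP's own ray follows. With
    ``radial_rescale`` the output magnitude is ``(r - dz) / (l - dz)``
    where ``r`` is the COP distance and ``l`` the radial limit, clamped to
    [0, 1] — continuous at the deadzone boundary and saturating at the
    stability limit. ``hard_zero`` keeps the plain normalized vector and
    zeroes it inside the deadzone (discontinuous, matches some commercial
    mappings).
    """
    x, y = float(cop_mm[0]), float(cop_mm[1])
    r = math.hypot(x, y)
    dz = cal.deadzone_radius
    if r <= dz or r == 0.0:
        return JoystickState(0.0, 0.0)
    nx = x / (cal.limit_R if x > 0 else cal.limit_L)
    ny = y / (cal.limit_A if y > 0 else cal.limit_P)
    rn = math.hypot(nx, ny)  # normalized magnitude; 1 at the limit surface
    if deadzone_mode == "hard_zero":
        mag = min(rn, 1.0)
    elif deadzone_mode == "radial_rescale":
        limit_along_ray = r / rn
        mag = min(max((r - dz) / (limit_along_ray - dz), 0.0), 1.0)
    else:
        raise ParameterError(f"unknown deadzone mode {deadzone_mode!r}")
    return JoystickState(u=nx / rn * mag, v=ny / rn * mag)


# ---------------------------------------------------------------------------
# Course and game state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerrainSegment:
    start_m: float
    drag: float  # 1/s

    def __post_init__(self) -> None:
        if self.drag < 0:
            raise ParameterError("terrain drag must be non-negative")


@dataclass(frozen=True)
class Course:
    """A race course: length, herring positions (course, lateral) in m,
    terrain drag per segment, lateral half-width, time limit."""

    length_m: float = 200.0
    half_width_m: float = 5.0
    herrings: tuple[tuple[float, float], ...] = ()
    segments: tuple[TerrainSegment, ...] = (TerrainSegment(0.0, 0.3),)
    time_limit_s: float = 120.0

    def __post_init__(self) -> None:
        if self.length_m <= 0 or self.half_width_m <= 0:
            raise ParameterError("course dimensions must be positive")
        if self.time_limit_s <= 0:
            raise ParameterError("time limit must be positive")
        if not self.segments or self.segments[0].start_m > 0:
            raise ParameterError("terrain must cover the course from 0 m")
        starts = [s.start_m for s in self.segments]
        if starts != sorted(starts):
            raise ParameterError("terrain segments must be sorted by start")
        for s, lat in self.herrings:
            if not (0 <= s <= self.length_m and abs(lat) <= self.half_width_m):
                raise ParameterError(f"herring at ({s}, {lat}) outside course bounds")

    def drag_at(self, position_m: float) -> float:
        drag = self.segments[0].drag
        for seg in self.segments:
            if seg.start_m <= position_m:
                drag = seg.drag
            else:
                break
        return drag

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "length_m": self.length_m,
            "half_width_m": self.half_width_m,
            "herrings": [list(h) for h in self.herrings],
            "segments": [[s.start_m, s.drag] for s in self.segments],
            "time_limit_s": self.time_limit_s,
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Course":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            length_m=data["length_m"],
            half_width_m=data["half_width_m"],
            herrings=tuple(tuple(h) for h in data["herrings"]),
            segments=tuple(TerrainSegment(*s) for s in data["segments"]),
            time_limit_s=data["time_limit_s"],
        )


def slalom_course(
    length_m: float = 200.0,
    herring_spacing_m: float = 10.0,
    lateral_amplitude_m: float = 2.0,
    time_limit_s: float = 120.0,
) -> Course:
    """A gated slalom: herrings alternate left/right, eliciting the
    side-to-side weight shifts the training targets."""
    positions = np.arange(herring_spacing_m, length_m, herring_spacing_m)
    herrings = tuple(
        (float(s), float(lateral_amplitude_m * (-1) ** i))
        for i, s in enumerate(positions)
    )
    return Course(
        length_m=length_m,
        herrings=herrings,
        segments=(
            TerrainSegment(0.0, 0.3),
            TerrainSegment(length_m * 0.3, 0.5),
            TerrainSegment(length_m * 0.6, 0.2),
        ),
        time_limit_s=time_limit_s,
    )


@dataclass(frozen=True)
class GameState:
    course_position: float = 0.0   # m
    lateral_position: float = 0.0  # m
    speed: float = 0.0             # m/s
    herrings_collected: int = 0
    collected: frozenset[int] = frozenset()
    elapsed: float = 0.0           # s
    resets: int = 0
    stuck_timer: float = 0.0       # s below stuck_speed
    finished: bool = False


class GamePerformance(NamedTuple):
    score: int
    herrings: int
    time_s: float
    resets: int
    finished: bool
    distance_m: float


def step_game(
    state: GameState,
    js: JoystickState,
    course: Course,
    params: GameConfig = DEFAULT_CONFIG.game,
    dt: float | None = None,
) -> GameState:
    """Advance the game by one fixed step; raises on a finished game."""
    if state.finished:
        raise StateError("cannot step a finished game")
    dt = dt if dt is not None else 1.0 / params.step_hz
    if dt <= 0:
        raise ParameterError("dt must be positive")
    drag = course.drag_at(state.course_position)
    accel = (
        params.a_fwd * max(js.v, 0.0)
        + params.a_brake * min(js.v, 0.0)
        - drag * state.speed
    )
    speed = min(max(state.speed + accel * dt, 0.0), params.speed_max)
    lateral = min(
        max(
            state.lateral_position + params.k_steer * js.u * speed * dt,
            -course.half_width_m,
        ),
        course.half_width_m,
    )
    position = state.course_position + speed * dt
    elapsed = state.elapsed + dt

    collected = state.collected
    for i, (hs, hl) in enumerate(course.herrings):
        if i not in collected and math.hypot(hs - position, hl - lateral) <= params.capture_radius:
            collected = collected | {i}

    stuck_timer = state.stuck_timer + dt if speed < params.stuck_speed else 0.0
    resets = state.resets
    if stuck_timer >= params.stuck_time_s:
        resets += 1
        stuck_timer = 0.0

    finished = position >= course.length_m or elapsed >= course.time_limit_s
    return GameState(
        course_position=position,
        lateral_position=lateral,
        speed=speed,
        herrings_collected=len(collected),
        collected=collected,
        elapsed=elapsed,
        resets=resets,
        stuck_timer=stuck_timer,
        finished=finished,
    )


def run_session(
    cop_stream: COPTrajectory,
    cal: Calibration,
    course: Course,
    config: RunConfig = DEFAULT_CONFIG,
    log: list | None = None,
) -> tuple[GamePerformance, dict[str, float]]:
    """Replay a centered COP stream through the game.

    The stream is linearly resampled to the game step rate when the rates
    differ. Returns the performance summary and the elicited-excursion
    summary: the fraction of active (outside-deadzone) play time spent in
    each of the eight direction octants, plus the deadzone fraction of
    total time. Replays are deterministic.
    """
    if cop_stream.n_samples < 2:
        raise ContractError("empty COP stream")
    if not cop_stream.is_centered:
        raise ContractError("COP stream must be centered before gameplay")
    params = config.game
    xy = cop_stream.xy
    if abs(cop_stream.sampling_rate - params.step_hz) > 1e-9:
        t_src = np.arange(len(xy)) / cop_stream.sampling_rate
        t_dst = np.arange(0.0, t_src[-1] + 1e-12, 1.0 / params.step_hz)
        xy = np.column_stack(
            [np.interp(t_dst, t_src, xy[:, 0]), np.interp(t_dst, t_src, xy[:, 1])]
        )

    state = GameState()
    octant_counts = dict.fromkeys(OCTANTS, 0)
    deadzone_count = 0
    for sample in xy:
        js = cop_to_joystick(sample, cal, deadzone_mode=params.deadzone_mode)
        r = math.hypot(sample[0], sample[1])
        if r <= cal.deadzone_radius or r == 0.0:
            deadzone_count += 1
        else:
            angle = math.degrees(math.atan2(sample[1], sample[0])) % 360.0
            octant_counts[OCTANTS[int(round(angle / 45.0)) % 8]] += 1
        state = step_game(state, js, course, params)
        if log is not None:
            log.append(
                (
                    state.elapsed,
                    float(sample[0]),
                    float(sample[1]),
                    js.u,
                    js.v,
                    state.speed,
                    state.course_position,
                    state.herrings_collected,
                )
            )
        if state.finished:
            break

    time_bonus = (
        int(max(0.0, course.time_limit_s - state.elapsed))
        if state.course_position >= course.length_m
        else 0
    )
    perf = GamePerformance(
        score=10 * state.herrings_collected + time_bonus,
        herrings=state.herrings_collected,
        time_s=state.elapsed,
        resets=state.resets,
        finished=state.finished,
        distance_m=state.course_position,
    )
    n_active = sum(octant_counts.values())
    n_total = n_active + deadzone_count
    summary = {
        k: (v / n_active if n_active else 0.0) for k, v in octant_counts.items()
    }
    summary["deadzone"] = deadzone_count / n_total if n_total else 0.0
    return perf, summary
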