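"""Synthetic force-plate signals and cohorts.

Three layers of simulation make the toolkit testable end to end without
any recorded human data:

* **Quiet stance** — per-axis Ornstein-Uhlenbeck (mean-reverting) sway
  with exact discretization plus white measurement noise. The OU process
  is the simplest model with a stationary, tunable sway variance
  (``sigma^2 / (2 theta)``).
* **Excursion trials** — deterministic ramp-hold-return profiles along a
  chosen direction (single-direction trials), and a multi-directional
  "battery" trial that visits all four directions in one recording with
  sub-maximal repetitions, the pattern a limits-of-stability assessment
  elicits. The young-adult battery defaults are calibrated so that the
  aggregated metric battery lands on published normative values for
  healthy young adults.
* **Cohorts** — subject-level pre/post metric vectors drawn from
  correlated Gaussians parameterized by published elderly baselines and
  six-week balance-training effects, for exercising the statistics
  pipeline at realistic effect sizes.

The inverse force model :func:`cop_to_forces` distributes body weight
over the four cells with the bilinear-interpolation weights of the COP in
the sensor rectangle; it is an exact right-inverse of
:func:`posturekit.cop.compute_cop`.

Every generator is deterministic given its seed, which is recorded in the
output provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cop import COPTrajectory, OriginRef
from .errors import GeometryError, ParameterError
from .io import OutcomeTable, PlateGeometry, RawForceRecord, default_geometry

# ---------------------------------------------------------------------------
# Normative parameterizations (mm, mm/s, mm^2; mean, SD)
# ---------------------------------------------------------------------------

#: Baseline excursion metrics of healthy young adults (reference cohort).
YOUNG_BASELINE: dict[str, tuple[float, float]] = {
    "ml_total_path": (2530.42, 762.68),
    "ap_total_path": (2857.69, 520.12),
    "total_path": (4528.19, 988.28),
    "ml_sway_range": (264.55, 17.58),
    "ap_sway_range": (186.87, 13.13),
    "max_range_R": (130.30, 10.46),
    "max_range_L": (134.24, 8.69),
    "max_range_A": (81.26, 11.73),
    "max_range_P": (105.61, 12.11),
    "ml_mean_velocity": (63.44, 20.72),
    "ap_mean_velocity": (68.13, 21.62),
    "mean_velocity": (98.88, 36.62),
    "sway_area": (24658.91, 1607.95),
}

#: Baseline metrics of a community-dwelling elderly control cohort.
ELDERLY_CONTROL_BASELINE: dict[str, tuple[float, float]] = {
    "ml_total_path": (1609.97, 385.45),
    "ap_total_path": (1787.16, 441.68),
    "total_path": (2764.66, 564.11),
    "ml_sway_range": (181.97, 45.52),
    "ap_sway_range": (93.62, 19.83),
    "max_range_R": (99.29, 25.25),
    "max_range_L": (82.67, 30.06),
    "max_range_A": (39.02, 16.46),
    "max_range_P": (56.60, 24.01),
    "ml_mean_velocity": (35.62, 43.88),
    "ap_mean_velocity": (28.29, 28.25),
    "mean_velocity": (53.58, 62.36),
    "sway_area": (8518.03, 2482.06),
}

#: Baseline metrics of the elderly cohort assigned to training.
ELDERLY_EXPERIMENTAL_BASELINE: dict[str, tuple[float, float]] = {
    "ml_total_path": (1413.31, 423.87),
    "ap_total_path": (1699.87, 509.24),
    "total_path": (2645.59, 711.54),
    "ml_sway_range": (166.00, 60.95),
    "ap_sway_range": (96.72, 37.77),
    "max_range_R": (81.52, 30.09),
    "max_range_L": (84.47, 33.77),
    "max_range_A": (49.62, 24.31),
    "max_range_P": (39.86, 26.64),
    "ml_mean_velocity": (40.62, 33.88),
    "ap_mean_velocity": (39.03, 26.48),
    "mean_velocity": (59.81, 38.69),
    "sway_area": (8942.27, 6825.78),
}

#: Mean pre-to-post change after six weeks of game-based balance training.
TRAINING_EFFECTS: dict[str, float] = {
    "ml_total_path": 427.56,
    "ap_total_path": 863.04,
    "total_path": 918.80,
    "ml_sway_range": 75.58,
    "ap_sway_range": 16.53,
    "max_range_R": 42.13,
    "max_range_L": 33.46,
    "max_range_A": 20.28,
    "max_range_P": 9.73,
    "ml_mean_velocity": 24.45,
    "ap_mean_velocity": 22.37,
    "mean_velocity": 33.58,
    "sway_area": 4639.71,
}

#: Post-intervention SDs observed in the trained elderly cohort.
EXPERIMENTAL_POST_SD: dict[str, float] = {
    "ml_total_path": 492.46,
    "ap_total_path": 532.52,
    "total_path": 773.93,
    "ml_sway_range": 50.42,
    "ap_sway_range": 34.35,
    "max_range_R": 26.39,
    "max_range_L": 26.99,
    "max_range_A": 19.19,
    "max_range_P": 19.48,
    "ml_mean_velocity": 54.90,
    "ap_mean_velocity": 28.97,
    "mean_velocity": 44.91,
    "sway_area": 6716.52,
}

#: Post-period SDs observed in the untrained elderly cohort.
CONTROL_POST_SD: dict[str, float] = {
    "ml_total_path": 629.88,
    "ap_total_path": 373.94,
    "total_path": 722.43,
    "ml_sway_range": 40.88,
    "ap_sway_range": 28.85,
    "max_range_R": 19.29,
    "max_range_L": 29.36,
    "max_range_A": 22.17,
    "max_range_P": 19.94,
    "ml_mean_velocity": 54.90,
    "ap_mean_velocity": 32.49,
    "mean_velocity": 44.91,
    "sway_area": 4025.16,
}

#: Clinical outcomes: baseline (mean, SD), training effect, post SD.
OUTCOME_BASELINE = {"bbs": (39.90, 5.80), "tug_s": (17.08, 5.16), "reach_cm": (19.13, 5.34)}
OUTCOME_EFFECTS = {"bbs": 9.55, "tug_s": -3.95, "reach_cm": 4.68}
OUTCOME_POST_SD = {"bbs": 3.95, "tug_s": 3.39, "reach_cm": 4.40}

METRIC_PARAMETERS = list(YOUNG_BASELINE)


# ---------------------------------------------------------------------------
# Quiet stance: Ornstein-Uhlenbeck sway
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwaySimParams:
    """Mean-reverting sway model parameters.

    ``theta`` (1/s) is the relaxation rate toward the stance origin,
    ``sigma`` (mm/sqrt(s)) the noise intensity, per axis (ML, AP);
    ``noise_sd`` (mm) is additive white measurement noise. Stationary
    sway SD per axis is ``sigma / sqrt(2 theta)``.
    """

    theta: tuple[float, float] = (1.0, 1.0)
    sigma: tuple[float, float] = (4.0, 4.0)
    noise_sd: float = 0.1
    sampling_rate: float = 100.0
    duration: float = 30.0
    seed: int = 0
    process: str = "ou"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.theta):
            raise ParameterError("relaxation rates must be positive")
        if any(s < 0 for s in self.sigma):
            raise ParameterError("noise intensities must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("measurement noise SD must be non-negative")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ParameterError("duration and sampling rate must be positive")
        if self.process != "ou":
            raise ParameterError(f"unknown sway process {self.process!r}")


def simulate_quiet_stance(p: SwaySimParams) -> COPTrajectory:
    """Simulate quiet-stance sway about the stance origin.

    Uses the exact OU discretization
    ``x[k+1] = x[k] e^{-theta dt} + sigma sqrt((1 - e^{-2 theta dt}) / (2 theta)) eps``
    started from a stationary draw, plus white measurement noise. The
    returned trajectory is expressed relative to the stance origin.
    """
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / p.sampling_rate
    n = int(round(p.duration * p.sampling_rate)) + 1
    xy = np.empty((n, 2))
    for ax in range(2):
        theta, sigma = p.theta[ax], p.sigma[ax]
        stat_sd = sigma / np.sqrt(2.0 * theta)
        decay = np.exp(-theta * dt)
        step_sd = sigma * np.sqrt((1.0 - np.exp(-2.0 * theta * dt)) / (2.0 * theta))
        x = np.empty(n)
        x[0] = stat_sd * rng.standard_normal() if stat_sd > 0 else 0.0
        shocks = step_sd * rng.standard_normal(n - 1)
        for k in range(1, n):
            x[k] = x[k - 1] * decay + shocks[k - 1]
        xy[:, ax] = x
    if p.noise_sd > 0:
        xy += p.noise_sd * rng.standard_normal(xy.shape)
    return COPTrajectory(
        xy=xy,
        sampling_rate=p.sampling_rate,
        origin_reference=OriginRef((0.0, 0.0), "mean"),
        provenance={"generator": "quiet_stance_ou", "seed": p.seed},
    )


# ---------------------------------------------------------------------------
# Directed excursion trials
# ---------------------------------------------------------------------------

_DIRECTION_VECTORS = {
    "R": np.array([1.0, 0.0]),
    "L": np.array([-1.0, 0.0]),
    "A": np.array([0.0, 1.0]),
    "P": np.array([0.0, -1.0]),
}


@dataclass(frozen=True)
class MVESimParams:
    """One directed maximal-voluntary-excursion trial.

    The COP ramps from the stance origin to ``amplitude * (1 + overshoot)``
    along ``direction``, settles to ``amplitude`` over the hold, and ramps
    back; quiet-stance sway (if given) is superimposed.
    """

    direction: str = "A"
    amplitude: float = 80.0       # mm
    ramp_time: float = 1.0        # s
    hold_time: float = 1.0        # s
    return_time: float = 1.0      # s
    lead_in: float = 1.5          # s of quiet hold before the ramp
    tail: float = 0.5             # s after return
    overshoot: float = 0.0        # fraction of amplitude
    sway: SwaySimParams | None = None
    sampling_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTION_VECTORS:
            raise ParameterError("direction must be one of R, L, A, P")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")
        if min(self.ramp_time, self.hold_time, self.return_time) <= 0:
            raise ParameterError("ramp, hold and return times must be positive")
        if abs(self.overshoot) >= 0.5:
            raise ParameterError("|overshoot| must be < 0.5")


def _cosine_ramp(n: int) -> np.ndarray:
    """Smooth 0 -> 1 profile over n samples (half-cosine)."""
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))


def _excursion_profile(
    amplitude: float,
    peak: float,
    fs: float,
    ramp_time: float,
    hold_time: float,
    return_time: float,
) -> np.ndarray:
    """Scalar ramp-settle-return profile starting and ending at 0."""
    n_ramp = max(2, int(round(ramp_time * fs)))
    n_hold = max(1, int(round(hold_time * fs)))
    n_ret = max(2, int(round(return_time * fs)))
    ramp = peak * _cosine_ramp(n_ramp)
    hold = np.linspace(peak, amplitude, n_hold)
    ret = amplitude * (1.0 - _cosine_ramp(n_ret))
    return np.concatenate([ramp, hold, ret])


def simulate_mve_trial(p: MVESimParams) -> COPTrajectory:
    """Simulate a single-direction excursion trial relative to the stance
    origin. Without noise and overshoot, the directional maximum equals
    the target amplitude exactly."""
    fs = p.sampling_rate
    peak = p.amplitude * (1.0 + p.overshoot)
    profile = _excursion_profile(
        p.amplitude, peak, fs, p.ramp_time, p.hold_time, p.return_time
    )
    n_lead = int(round(p.lead_in * fs))
    n_tail = int(round(p.tail * fs))
    scalar = np.concatenate([np.zeros(n_lead), profile, np.zeros(n_tail)])
    xy = scalar[:, None] * _DIRECTION_VECTORS[p.direction][None, :]
    if p.sway is not None:
        duration = (len(scalar) - 1) / fs
        sway = simulate_quiet_stance(
            SwaySimParams(
                theta=p.sway.theta,
                sigma=p.sway.sigma,
                noise_sd=p.sway.noise_sd,
                sampling_rate=fs,
                duration=duration,
                seed=p.seed,
            )
        )
        xy = xy + sway.xy[: len(scalar)]
    return COPTrajectory(
        xy=xy,
        sampling_rate=fs,
        origin_reference=OriginRef((0.0, 0.0), "initial_window"),
        provenance={"generator": "mve_trial", "direction": p.direction, "seed": p.seed},
    )


# ---------------------------------------------------------------------------
# Multi-directional excursion battery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MVEBatteryParams:
    """One assessment trial that visits all four directions.

    A limits-of-stability trial alternates excursions toward each
    direction with quiet holds in between; only one excursion per side is
    maximal, the rest are sub-maximal repetitions. Amplitudes (mm) are
    the per-direction stability limits; ``ml_path`` / ``ap_path`` (mm)
    set the target per-axis sway paths, from which the sub-maximal
    repetition scale is derived (each out-and-back excursion of amplitude
    ``a`` contributes ``2a`` of axis path).

    Defaults are calibrated to healthy-young normative values: limits
    (R, L, A, P) = (130.30, 134.24, 81.26, 105.61) mm, axis paths
    (2530.42, 2857.69) mm, 5 ML and 8 AP excursions per side in 60 s.
    """

    amp_R: float = YOUNG_BASELINE["max_range_R"][0]
    amp_L: float = YOUNG_BASELINE["max_range_L"][0]
    amp_A: float = YOUNG_BASELINE["max_range_A"][0]
    amp_P: float = YOUNG_BASELINE["max_range_P"][0]
    ml_path: float = YOUNG_BASELINE["ml_total_path"][0]
    ap_path: float = YOUNG_BASELINE["ap_total_path"][0]
    n_ml: int = 5                 # excursions per ML side
    n_ap: int = 8                 # excursions per AP side
    duration: float = 60.0        # s
    ramp_time: float = 0.5        # s out, s back
    hold_time: float = 0.2        # s at the target
    amplitude_jitter: float = 0.03  # relative, uniform, per excursion
    sway_amplitude: tuple[float, float] = (1.0, 0.6)  # mm residual sway
    sway_freq_hz: tuple[float, float] = (0.25, 0.40)
    sampling_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.amp_R, self.amp_L, self.amp_A, self.amp_P) <= 0:
            raise ParameterError("all direction amplitudes must be positive")
        if self.n_ml < 1 or self.n_ap < 1:
            raise ParameterError("at least one excursion per side")
        if not 0 <= self.amplitude_jitter < 0.5:
            raise ParameterError("amplitude_jitter must be in [0, 0.5)")


def _side_scales(full_equivalents: float, n: int) -> np.ndarray:
    """Per-excursion amplitude scales for one side: the last excursion is
    maximal (scale 1), earlier ones share the remaining path budget."""
    if n == 1:
        return np.array([full_equivalents])
    rest = (full_equivalents - 1.0) / (n - 1)
    if rest <= 0:
        raise ParameterError(
            "path target too small for the requested excursion count"
        )
    return np.array([rest] * (n - 1) + [1.0])


def simulate_mve_battery_trial(p: MVEBatteryParams) -> COPTrajectory:
    """Simulate one multi-directional excursion battery trial.

    Excursions toward R/L/A/P are interleaved (Bresenham-style so the two
    axes stay temporally mixed), separated by quiet holds that fill the
    trial to ``duration``. Amplitudes receive a uniform relative jitter;
    a small two-tone sinusoidal residual sway is superimposed.
    """
    rng = np.random.default_rng(p.seed)
    fs = p.sampling_rate

    e_ml = p.ml_path / (2.0 * (p.amp_R + p.amp_L))
    e_ap = p.ap_path / (2.0 * (p.amp_A + p.amp_P))
    sides = {
        "R": p.amp_R * _side_scales(e_ml, p.n_ml),
        "L": p.amp_L * _side_scales(e_ml, p.n_ml),
        "A": p.amp_A * _side_scales(e_ap, p.n_ap),
        "P": p.amp_P * _side_scales(e_ap, p.n_ap),
    }
    # interleave ML (R, L alternating) and AP (A, P alternating) excursions
    ml_queue = [d for i in range(p.n_ml) for d in ("R", "L")]
    ap_queue = [d for i in range(p.n_ap) for d in ("A", "P")]
    order: list[str] = []
    acc = 0.0
    ratio = len(ap_queue) / (len(ap_queue) + len(ml_queue))
    while ml_queue or ap_queue:
        acc += ratio
        if ap_queue and (acc >= 1.0 or not ml_queue):
            order.append(ap_queue.pop(0))
            acc -= 1.0
        else:
            order.append(ml_queue.pop(0))
    used = {d: 0 for d in sides}

    n_exc = len(order)
    t_active = n_exc * (2 * p.ramp_time + p.hold_time)
    gap = (p.duration - t_active) / (n_exc + 1)
    if gap < 0:
        raise ParameterError("excursions do not fit in the trial duration")
    n_gap = max(1, int(round(gap * fs)))

    pieces = [np.zeros((n_gap, 2))]
    for d in order:
        amp = sides[d][used[d]]
        used[d] += 1
        if p.amplitude_jitter > 0:
            amp *= 1.0 + rng.uniform(-p.amplitude_jitter, p.amplitude_jitter)
        profile = _excursion_profile(
            amp, amp, fs, p.ramp_time, p.hold_time, p.ramp_time
        )
        pieces.append(profile[:, None] * _DIRECTION_VECTORS[d][None, :])
        pieces.append(np.zeros((n_gap, 2)))
    xy = np.concatenate(pieces, axis=0)

    t = np.arange(len(xy)) / fs
    for ax in range(2):
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        xy[:, ax] += p.sway_amplitude[0] * np.sin(
            2 * np.pi * p.sway_freq_hz[0] * t + phase1
        ) + p.sway_amplitude[1] * np.sin(2 * np.pi * p.sway_freq_hz[1] * t + phase2)

    return COPTrajectory(
        xy=xy,
        sampling_rate=fs,
        origin_reference=OriginRef((0.0, 0.0), "initial_window"),
        provenance={"generator": "mve_battery", "seed": p.seed},
    )


def simulate_mve_battery_session(
    params: MVEBatteryParams = MVEBatteryParams(),
    n_trials: int = 12,
    seed: int = 0,
) -> list[COPTrajectory]:
    """A full assessment session of battery trials with per-trial seeds."""
    children = np.random.SeedSequence(seed).spawn(n_trials)
    out = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(
            simulate_mve_battery_trial(
                MVEBatteryParams(
                    **{
                        **{
                            f: getattr(params, f)
                            for f in params.__dataclass_fields__
                        },
                        "seed": sub_seed,
                    }
                )
            )
        )
    return out


# ---------------------------------------------------------------------------
# Inverse force model
# ---------------------------------------------------------------------------

def cop_to_forces(
    traj: COPTrajectory,
    body_weight_n: float,
    geom: PlateGeometry | None = None,
    **ids,
) -> RawForceRecord:
    """Distribute a constant body weight over the four cells so that the
    force-weighted mean of the sensor positions reproduces the COP.

    Per sample, the cell forces are the bilinear-interpolation weights of
    the COP within the sensor rectangle times the body weight: all
    non-negative, summing to the weight, and an exact right-inverse of
    :func:`posturekit.cop.compute_cop`. Centered trajectories are mapped
    back to the plate frame using their recorded origin reference.
    """
    if body_weight_n <= 0:
        raise ParameterError("body weight must be positive")
    geom = geom or default_geometry()
    xy = traj.xy + np.asarray(traj.origin_reference.point)
    xmin, xmax, ymin, ymax = geom.bounds
    bad = np.argwhere(
        (xy[:, 0] <= xmin) | (xy[:, 0] >= xmax) | (xy[:, 1] <= ymin) | (xy[:, 1] >= ymax)
    )
    if bad.size:
        i = int(bad[0, 0])
        raise GeometryError(
            f"COP sample {i} at ({xy[i, 0]:.2f}, {xy[i, 1]:.2f}) mm is not "
            f"strictly inside the sensor rectangle "
            f"[{xmin}, {xmax}] x [{ymin}, {ymax}]"
        )
    u = (xy[:, 0] - xmin) / (xmax - xmin)
    v = (xy[:, 1] - ymin) / (ymax - ymin)
    forces = np.empty((len(xy), 4))
    for j, (cx, cy) in enumerate(geom.positions):
        wx = u if cx == xmax else 1.0 - u
        wy = v if cy == ymax else 1.0 - v
        forces[:, j] = body_weight_n * wx * wy
    return RawForceRecord(
        forces=forces,
        sampling_rate=traj.sampling_rate,
        geometry=geom,
        **ids,
    )


# ---------------------------------------------------------------------------
# Metric-level cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One simulated group: size, baseline (mean, SD) per parameter,
    additive pre-to-post effect, and post-phase SDs."""

    n: int
    baseline: Mapping[str, tuple[float, float]]
    effect: Mapping[str, float] = field(default_factory=dict)
    post_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("group size must be >= 2")
        for name, (mu, sd) in self.baseline.items():
            if sd <= 0:
                raise ParameterError(f"{name}: baseline SD must be positive")


@dataclass(frozen=True)
class CohortSimParams:
    """Pre/post cohort at the metrics level.

    Per subject and parameter, (pre, post) are drawn from a bivariate
    normal with the group's baseline mean/SD, the group effect added to
    the post mean, the post SD (falling back to baseline SD), and
    test-retest correlation ``rho``. Defaults reproduce a trained
    experimental group (n=15) against an untrained control (n=14) with
    published six-week training effects; the control group receives no
    effect.
    """

    groups: Mapping[str, GroupSpec] = field(
        default_factory=lambda: {
            "experimental": GroupSpec(
                n=15,
                baseline=ELDERLY_EXPERIMENTAL_BASELINE,
                effect=TRAINING_EFFECTS,
                post_sd=EXPERIMENTAL_POST_SD,
            ),
            "control": GroupSpec(
                n=14,
                baseline=ELDERLY_CONTROL_BASELINE,
                effect={},
                post_sd=CONTROL_POST_SD,
            ),
        }
    )
    rho: float = 0.7
    simulate_outcomes: bool = True
    outcome_effect_groups: tuple[str, ...] = ("experimental",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ParameterError("|rho| must be < 1")


@dataclass
class CohortResult:
    """Simulated cohort: long-format metrics and an outcome table."""

    metrics: pd.DataFrame      # subject_id, group, phase, parameter, value
    outcomes: OutcomeTable | None
    n_clipped: int
    seed: int

    def wide(self, phase: str) -> pd.DataFrame:
        """Wide per-subject table (one column per parameter) for a phase."""
        sel = self.metrics[self.metrics.phase == phase]
        wide = sel.pivot_table(
            index=["subject_id", "group"], columns="parameter", values="value"
        ).reset_index()
        wide.columns.name = None
        return wide


def _draw_pre_post(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd_pre: float,
    sd_post: float,
    effect: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    pre = mean + sd_pre * z1
    post = mean + effect + sd_post * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    return pre, post


def simulate_cohort(p: CohortSimParams = CohortSimParams()) -> CohortResult:
    """Draw a pre/post cohort; negative metric draws are clipped at 0 and
    counted (rare at the default parameterization), BBS is clipped to its
    0-56 point scale, and TUG times are floored at 0.1 s."""
    rng = np.random.default_rng(p.seed)
    rows = []
    n_clipped = 0
    subject_counter = 0
    outcome_rows = []
    for group, spec in p.groups.items():
        ids = [f"{group[:3]}{subject_counter + i + 1:03d}" for i in range(spec.n)]
        subject_counter += spec.n
        for param, (mu, sd) in spec.baseline.items():
            effect = float(spec.effect.get(param, 0.0))
            sd_post = float(spec.post_sd.get(param, sd))
            pre, post = _draw_pre_post(rng, spec.n, mu, sd, sd_post, effect, p.rho)
            n_clipped += int(np.sum(pre < 0) + np.sum(post < 0))
            pre = np.maximum(pre, 0.0)
            post = np.maximum(post, 0.0)
            for sid, a, b in zip(ids, pre, post):
                rows.append((sid, group, "pre", param, float(a)))
                rows.append((sid, group, "post", param, float(b)))
        if p.simulate_outcomes:
            apply_effect = group in p.outcome_effect_groups
            vals = {}
            for name, (mu, sd) in OUTCOME_BASELINE.items():
                effect = OUTCOME_EFFECTS[name] if apply_effect else 0.0
                sd_post = OUTCOME_POST_SD[name] if apply_effect else sd
                pre, post = _draw_pre_post(
                    rng, spec.n, mu, sd, sd_post, effect, p.rho
                )
                if name == "bbs":
                    clip_pre, clip_post = np.clip(pre, 0, 56), np.clip(post, 0, 56)
                elif name == "tug_s":
                    clip_pre, clip_post = np.maximum(pre, 0.1), np.maximum(post, 0.1)
                else:
                    clip_pre, clip_post = np.maximum(pre, 0.0), np.maximum(post, 0.0)
                n_clipped += int(
                    np.sum(clip_pre != pre) + np.sum(clip_post != post)
                )
                vals[name] = (clip_pre, clip_post)
            for i, sid in enumerate(ids):
                for phase_idx, phase in enumerate(("pre", "post")):
                    outcome_rows.append(
                        {
                            "subject_id": sid,
                            "group": group,
                            "phase": phase,
                            "bbs": float(vals["bbs"][phase_idx][i]),
                            "tug_s": float(vals["tug_s"][phase_idx][i]),
                            "reach_cm": float(vals["reach_cm"][phase_idx][i]),
                        }
                    )
    metrics = pd.DataFrame(
        rows, columns=["subject_id", "group", "phase", "parameter", "value"]
    )
    outcomes = (
        OutcomeTable(pd.DataFrame(outcome_rows)) if p.simulate_outcomes else None
    )
    return CohortResult(
        metrics=metrics, outcomes=outcomes, n_clipped=n_clipped, seed=p.seed
    )
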