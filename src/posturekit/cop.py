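"""Center-of-pressure trajectories from four-channel vertical forces.

With uni-axial vertical load cells under a rigid plate, the COP is the
force-weighted mean of the sensor positions:

    x = sum_i F_i x_i / sum_i F_i,    y = sum_i F_i y_i / sum_i F_i

which always lies inside the sensor rectangle for non-negative forces.
Samples whose total vertical load falls below a configurable threshold
(default 50 N) are excluded: near-zero load makes the quotient above
numerically meaningless (plate effectively unloaded).

Trajectories are centered before range metrics are computed; the default
origin is the mean COP of the trial's first second (the quiet hold before
an excursion), falling back to the whole-trial mean for very short trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy import signal

from .config import DEFAULT_CONFIG, RunConfig
from .errors import ContractError, LoadError, ParameterError, SensorError
from .io import RawForceRecord

NEGATIVE_FORCE_TOLERANCE_N = 1.0  # uni-axial cells cannot pull; allow ADC noise

_CENTERED_METHODS = ("mean", "initial_window")


@dataclass(frozen=True)
class OriginRef:
    """The point subtracted to center a trajectory, and how it was chosen."""

    point: tuple[float, float]
    method: str  # "plate_origin" | "mean" | "initial_window"


@dataclass
class COPTrajectory:
    """Planar COP time series in mm, x = ML (+right), y = AP (+anterior)."""

    xy: np.ndarray
    sampling_rate: float
    origin_reference: OriginRef = field(
        default_factory=lambda: OriginRef((0.0, 0.0), "plate_origin")
    )
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ContractError("trajectory must be an (n, 2) array")
        if self.xy.shape[0] < 2:
            raise ContractError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.xy)):
            raise ContractError("trajectory coordinates must be finite")
        if self.sampling_rate <= 0:
            raise ContractError("sampling_rate must be positive")

    @property
    def x_ml(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y_ap(self) -> np.ndarray:
        return self.xy[:, 1]

    @property
    def n_samples(self) -> int:
        return int(self.xy.shape[0])

    @property
    def duration(self) -> float:
        """Trial duration in s, counted as inter-sample intervals."""
        return (self.n_samples - 1) / self.sampling_rate

    @property
    def is_centered(self) -> bool:
        return self.origin_reference.method in _CENTERED_METHODS


def compute_cop(
    record: RawForceRecord,
    config: RunConfig = DEFAULT_CONFIG,
    drop_low_load: bool = True,
) -> COPTrajectory:
    """Convert a force record to an uncentered COP trajectory.

    Samples with total force below ``config.min_total_force_n`` are dropped
    (and counted in provenance) when ``drop_low_load`` is set; otherwise the
    first offending sample raises :class:`LoadError`. A channel more
    negative than -1 N indicates a sensor fault and raises
    :class:`SensorError`.
    """
    forces = record.forces
    if np.any(forces < -NEGATIVE_FORCE_TOLERANCE_N):
        i, j = np.argwhere(forces < -NEGATIVE_FORCE_TOLERANCE_N)[0]
        raise SensorError(
            f"channel {j + 1} reports {forces[i, j]:.2f} N at sample {i}; "
            "uni-axial cells cannot pull"
        )
    total = forces.sum(axis=1)
    low = total < config.min_total_force_n
    if np.any(low):
        if not drop_low_load:
            idx = int(np.argmax(low))
            raise LoadError(
                f"total force {total[idx]:.1f} N below threshold "
                f"{config.min_total_force_n} N at sample {idx}"
            )
        forces = forces[~low]
        total = total[~low]
    if forces.shape[0] < 2:
        raise LoadError("fewer than 2 samples above the minimum-load threshold")
    pos = record.geometry.positions  # (4, 2)
    xy = (forces @ pos) / total[:, None]
    xmin, xmax, ymin, ymax = record.geometry.bounds
    eps = 1e-9
    if np.any(
        (xy[:, 0] < xmin - eps)
        | (xy[:, 0] > xmax + eps)
        | (xy[:, 1] < ymin - eps)
        | (xy[:, 1] > ymax + eps)
    ):
        # cannot happen for clamped non-negative forces; guards sensor faults
        raise SensorError("COP left the sensor hull; check channel mapping")
    traj = COPTrajectory(
        xy=xy,
        sampling_rate=record.sampling_rate,
        origin_reference=OriginRef((0.0, 0.0), "plate_origin"),
        provenance={
            "subject_id": record.subject_id,
            "trial_id": record.trial_id,
            "direction": record.direction_label,
            "phase": record.phase_label,
            "dropped_low_load": int(np.sum(low)),
        },
    )
    if config.filter.enabled:
        traj = lowpass_filter(traj, config.filter.cutoff_hz, config.filter.order)
    return traj


def center_trajectory(
    traj: COPTrajectory,
    reference: str = "initial_window",
    window_s: float = 1.0,
) -> COPTrajectory:
    """Subtract a reference point so directional excursions are measured
    from the stance origin.

    ``reference`` is ``"mean"`` (whole-trial mean) or ``"initial_window"``
    (mean of the first ``window_s`` seconds — the quiet hold). Trials
    shorter than ``2 * window_s`` fall back to the whole-trial mean.
    Idempotent: re-centering a centered trajectory subtracts (numerically)
    zero.
    """
    if reference not in _CENTERED_METHODS:
        raise ParameterError(f"unknown centering reference {reference!r}")
    method = reference
    if reference == "initial_window":
        if window_s <= 0:
            raise ParameterError("window_s must be positive")
        if traj.duration < 2 * window_s:
            method = "mean"
    if method == "mean":
        ref = traj.xy.mean(axis=0)
    else:
        n = max(2, int(round(window_s * traj.sampling_rate)))
        ref = traj.xy[:n].mean(axis=0)
    prev = np.asarray(traj.origin_reference.point)
    return replace(
        traj,
        xy=traj.xy - ref,
        origin_reference=OriginRef(tuple(prev + ref), reference),
        provenance=dict(traj.provenance),
    )


def lowpass_filter(
    traj: COPTrajectory, cutoff_hz: float, order: int = 4
) -> COPTrajectory:
    """Zero-phase Butterworth low-pass per axis (forward-backward filter).

    Length-preserving and DC-preserving; disabled by default since the
    platform applies no analogue filtering beyond the ADC.
    """
    nyquist = traj.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff must be in (0, {nyquist}) Hz, got {cutoff_hz}"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=traj.sampling_rate, output="sos")
    xy = np.column_stack(
        [signal.sosfiltfilt(sos, traj.xy[:, 0]), signal.sosfiltfilt(sos, traj.xy[:, 1])]
    )
    prov = dict(traj.provenance)
    prov["filter"] = {"cutoff_hz": cutoff_hz, "order": order, "type": "butterworth_zero_phase"}
    return replace(traj, xy=xy, provenance=prov)
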