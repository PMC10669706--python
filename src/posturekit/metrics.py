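"""Stabilogram metrics for maximal-voluntary-excursion and stance trials.

The battery quantifies COP migration per trial:

* total path length — sum of Euclidean distances between successive COP
  locations; per-axis path lengths sum the absolute successive
  differences along ML and AP separately
* mean sway velocity — path length divided by trial duration, planar and
  per axis
* sway range — max minus min along each axis; directional maxima are the
  largest excursions to the subject's right/left/anterior/posterior from
  the stance origin (floored at zero for unvisited directions)
* sway area — area of the 95% confidence ellipse of the (ML, AP) point
  cloud, ``pi * q * sqrt(det(S))`` with S the sample covariance and q the
  chi-square(2 df) quantile at the confidence level (5.991 at 95%)

Range and directional metrics require a centered trajectory so that
"excursion to the anterior" is measured from the stance origin rather
than an arbitrary plate corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DEFAULT_CONFIG, RunConfig
from .cop import COPTrajectory
from .errors import ContractError, ParameterError

#: Column vocabulary used by every exported metrics table, in report order.
TABLE_COLUMNS = {
    "ml_total_path": "M/L total path",
    "ap_total_path": "A/P total path",
    "total_path": "Total path",
    "ml_sway_range": "M/L sway range",
    "ap_sway_range": "A/P sway range",
    "max_range_R": "Max range to R",
    "max_range_L": "Max range to L",
    "max_range_A": "Max range to A",
    "max_range_P": "Max range to P",
    "ml_mean_velocity": "M/L mean velocity",
    "ap_mean_velocity": "A/P mean velocity",
    "mean_velocity": "Mean velocity",
    "sway_area": "COP sway area",
}

#: The 13 metric field names, in table order (duration is bookkeeping).
METRIC_FIELDS = list(TABLE_COLUMNS)


@dataclass(frozen=True)
class SwayMetrics:
    """The per-trial (or aggregated) parameter battery.

    Distances in mm, velocities in mm/s, area in mm^2, duration in s.
    """

    ml_total_path: float
    ap_total_path: float
    total_path: float
    ml_sway_range: float
    ap_sway_range: float
    max_range_R: float
    max_range_L: float
    max_range_A: float
    max_range_P: float
    ml_mean_velocity: float
    ap_mean_velocity: float
    mean_velocity: float
    sway_area: float
    duration: float
    area_degenerate: bool = False

    def as_dict(self, table_names: bool = False) -> dict[str, float]:
        if table_names:
            return {TABLE_COLUMNS[k]: getattr(self, k) for k in METRIC_FIELDS}
        return {k: getattr(self, k) for k in METRIC_FIELDS}


class EllipseResult(NamedTuple):
    area: float
    degenerate: bool


def _require_samples(traj: COPTrajectory, n: int) -> None:
    if traj.n_samples < n:
        raise ContractError(f"operation needs at least {n} samples")


def total_path_length(traj: COPTrajectory) -> float:
    """Planar sway path: sum of Euclidean steps between successive samples."""
    _require_samples(traj, 2)
    steps = np.diff(traj.xy, axis=0)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def axis_path_length(traj: COPTrajectory, axis: str) -> float:
    """Per-axis sway path: sum of absolute successive differences."""
    _require_samples(traj, 2)
    col = _axis_column(axis)
    return float(np.sum(np.abs(np.diff(traj.xy[:, col]))))


def mean_sway_velocity(traj: COPTrajectory, axis: str = "planar") -> float:
    """Sway path divided by trial duration (mm/s)."""
    if traj.n_samples < 2:
        raise ContractError("velocity undefined for a single-sample trajectory")
    duration = traj.duration
    if duration <= 0:
        raise ContractError("velocity undefined for zero duration")
    if axis == "planar":
        return total_path_length(traj) / duration
    return axis_path_length(traj, axis) / duration


def sway_range(traj: COPTrajectory, axis: str) -> float:
    """Max minus min along the chosen axis (mm); needs a centered trajectory."""
    _require_centered(traj)
    col = _axis_column(axis)
    vals = traj.xy[:, col]
    return float(vals.max() - vals.min())


def directional_max_range(traj: COPTrajectory) -> tuple[float, float, float, float]:
    """Largest excursions (R, L, A, P) from the stance origin, mm, each
    floored at 0 when the direction is never visited."""
    _require_centered(traj)
    x, y = traj.xy[:, 0], traj.xy[:, 1]
    return (
        float(max(x.max(), 0.0)),
        float(max(-x.min(), 0.0)),
        float(max(y.max(), 0.0)),
        float(max(-y.min(), 0.0)),
    )


def confidence_ellipse(
    traj: COPTrajectory | np.ndarray,
    level: float = 0.95,
    method: str = "chi2",
) -> EllipseResult:
    """Area of the confidence ellipse of the COP point cloud.

    ``method="chi2"`` uses the large-sample chi-square(2) quantile
    (appropriate for trials with thousands of samples at 100 Hz);
    ``method="f"`` uses the small-sample F-based prediction-ellipse
    scaling ``2 (n-1)/(n-2) F_{2, n-2}(level)``. Degenerate (collinear)
    clouds yield area 0 with the flag set.
    """
    xy = traj.xy if isinstance(traj, COPTrajectory) else np.asarray(traj, dtype=float)
    n = xy.shape[0]
    if n < 3:
        raise ContractError("confidence ellipse needs at least 3 samples")
    if not 0 < level < 1:
        raise ParameterError("confidence level must be in (0, 1)")
    if method == "chi2":
        q = sps.chi2.ppf(level, df=2)
    elif method == "f":
        if n < 4:
            raise ContractError("F-based ellipse needs at least 4 samples")
        q = 2.0 * (n - 1) / (n - 2) * sps.f.ppf(level, 2, n - 2)
    else:
        raise ParameterError(f"unknown ellipse method {method!r}")
    cov = np.cov(xy, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    # relative tolerance: collinear clouds give det ~ 0 up to rounding
    scale = max(float(cov[0, 0]), float(cov[1, 1]), 1e-300)
    if det <= 1e-12 * scale**2:
        return EllipseResult(0.0, True)
    return EllipseResult(float(np.pi * q * np.sqrt(det)), False)


def confidence_ellipse_area(
    traj: COPTrajectory | np.ndarray, level: float = 0.95, method: str = "chi2"
) -> float:
    return confidence_ellipse(traj, level=level, method=method).area


def compute_all(traj: COPTrajectory, config: RunConfig = DEFAULT_CONFIG) -> SwayMetrics:
    """Populate the full battery for one centered trial."""
    _require_centered(traj)
    ml_path = axis_path_length(traj, "ML")
    ap_path = axis_path_length(traj, "AP")
    tot_path = total_path_length(traj)
    duration = traj.duration
    r, l, a, p = directional_max_range(traj)
    if config.velocity.mode == "axis_sum":
        planar_vel = (ml_path + ap_path) / duration
    else:
        planar_vel = tot_path / duration
    area = confidence_ellipse(
        traj, level=config.ellipse.level, method=config.ellipse.method
    )
    return SwayMetrics(
        ml_total_path=ml_path,
        ap_total_path=ap_path,
        total_path=tot_path,
        ml_sway_range=sway_range(traj, "ML"),
        ap_sway_range=sway_range(traj, "AP"),
        max_range_R=r,
        max_range_L=l,
        max_range_A=a,
        max_range_P=p,
        ml_mean_velocity=ml_path / duration,
        ap_mean_velocity=ap_path / duration,
        mean_velocity=planar_vel,
        sway_area=area.area,
        duration=duration,
        area_degenerate=area.degenerate,
    )


def aggregate_metrics(metrics: Sequence[SwayMetrics]) -> SwayMetrics:
    """Field-wise arithmetic mean of per-trial metrics (the "computed for
    each trial and then averaged" stage)."""
    if not metrics:
        raise ContractError("cannot aggregate zero trials")
    means = {
        f: float(np.mean([getattr(m, f) for m in metrics]))
        for f in METRIC_FIELDS + ["duration"]
    }
    return SwayMetrics(**means, area_degenerate=any(m.area_degenerate for m in metrics))


def metrics_table(rows: dict[str, SwayMetrics]) -> pd.DataFrame:
    """Flat table keyed by row label with the standard column vocabulary."""
    return pd.DataFrame(
        {label: m.as_dict(table_names=True) for label, m in rows.items()}
    ).T[list(TABLE_COLUMNS.values())]


def _axis_column(axis: str) -> int:
    if axis in ("ML", "ml", "x"):
        return 0
    if axis in ("AP", "ap", "y"):
        return 1
    raise ParameterError(f"axis must be 'ML' or 'AP', got {axis!r}")


def _require_centered(traj: COPTrajectory) -> None:
    if not traj.is_centered:
        raise ContractError(
            "trajectory is uncentered; apply cop.center_trajectory first so "
            "directional excursions are measured from the stance origin"
        )
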