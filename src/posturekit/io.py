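"""Reading and writing force-plate data, session manifests, and outcomes.

The plate is instrumented with four uni-axial load cells at the corners of
a rigid rectangular surface; each acquisition file is a delimited UTF-8
table with header ``time_s,f1_N,f2_N,f3_N,f4_N`` whose channel order is
tied to the order of :attr:`PlateGeometry.sensor_positions`. Session
manifests (YAML) organize trials per subject/phase/direction, and outcome
tables (CSV) hold the clinical scales: Berg Balance Scale (0-56 points),
Timed-Up-and-Go (s), functional reach (cm).

Axis convention, fixed across the toolkit: +x = subject's right (ML),
+y = anterior (AP), coordinates in mm in the plate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    FormatError,
    IntegrityError,
    RangeError,
    ResolutionError,
)

FORCE_COLUMNS = ["time_s", "f1_N", "f2_N", "f3_N", "f4_N"]
GROUPS = ("young", "experimental", "control")

BBS_MIN, BBS_MAX = 0.0, 56.0


# ---------------------------------------------------------------------------
# Plate geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateGeometry:
    """Positions of the four load cells in the plate frame (mm).

    The cells must form a non-degenerate axis-aligned rectangle; the i-th
    position corresponds to force channel ``f{i+1}_N`` in data files, so
    channel-to-corner assignment is always explicit, never positional
    convention alone.
    """

    sensor_positions: tuple[tuple[float, float], ...]
    plate_origin_convention: str = "front-left sensor at (0, 0)"
    axis_convention: str = "+x = subject's right (ML), +y = anterior (AP)"

    def __post_init__(self) -> None:
        pos = np.asarray(self.sensor_positions, dtype=float)
        if pos.shape != (4, 2):
            raise ValueError("exactly 4 planar sensor positions required")
        if not np.all(np.isfinite(pos)):
            raise ValueError("sensor positions must be finite")
        xs, ys = np.unique(pos[:, 0]), np.unique(pos[:, 1])
        if len(xs) != 2 or len(ys) != 2:
            raise ValueError("sensors must form an axis-aligned rectangle")
        corners = {(x, y) for x in xs for y in ys}
        if {tuple(p) for p in pos} != corners or len({tuple(p) for p in pos}) != 4:
            raise ValueError("sensors must occupy the 4 distinct rectangle corners")
        if (xs[1] - xs[0]) * (ys[1] - ys[0]) <= 0:
            raise ValueError("sensor rectangle must have positive area")

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self.sensor_positions, dtype=float)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the sensor rectangle, mm."""
        pos = self.positions
        return (
            float(pos[:, 0].min()),
            float(pos[:, 0].max()),
            float(pos[:, 1].min()),
            float(pos[:, 1].max()),
        )


def default_geometry(width_mm: float = 500.0, depth_mm: float = 500.0) -> PlateGeometry:
    """Square plate with sensors on the corners; channel order
    f1=(0,0), f2=(w,0), f3=(w,d), f4=(0,d)."""
    return PlateGeometry(
        sensor_positions=(
            (0.0, 0.0),
            (width_mm, 0.0),
            (width_mm, depth_mm),
            (0.0, depth_mm),
        )
    )


# ---------------------------------------------------------------------------
# Raw force records
# ---------------------------------------------------------------------------

@dataclass
class RawForceRecord:
    """Synchronously sampled vertical forces of the four cells (N).

    ``forces`` has shape (n, 4) with channel i under the i-th geometry
    sensor. Default sampling rate is 100 Hz, the platform's acquisition
    rate.
    """

    forces: np.ndarray
    sampling_rate: float = 100.0
    geometry: PlateGeometry = field(default_factory=default_geometry)
    subject_id: str | None = None
    trial_id: str | None = None
    direction_label: str | None = None
    phase_label: str | None = None

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 4:
            raise IntegrityError("forces must be an (n, 4) array")
        if self.forces.shape[0] < 2:
            raise IntegrityError("a force record needs at least 2 samples")
        if not np.all(np.isfinite(self.forces)):
            raise IntegrityError("forces must be finite")
        if self.sampling_rate <= 0:
            raise IntegrityError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.forces.shape[0])

    @property
    def total_force(self) -> np.ndarray:
        """Total vertical force per sample, N."""
        return self.forces.sum(axis=1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def read_force_record(
    path: str | Path,
    geometry: PlateGeometry,
    declared_rate: float | None = 100.0,
    **ids: str | None,
) -> RawForceRecord:
    """Read a delimited force file and validate it.

    The sampling rate is inferred from the time column and, when a rate is
    declared, checked against it within 1%.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"{path}: cannot parse as delimited text ({exc})") from exc
    if list(df.columns) != FORCE_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(FORCE_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    if len(df) < 2:
        raise IntegrityError(f"{path}: fewer than 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise IntegrityError(f"{path}: time column is not strictly increasing")
    inferred = 1.0 / float(np.median(dt))
    if declared_rate is not None and abs(inferred - declared_rate) > 0.01 * declared_rate:
        raise IntegrityError(
            f"{path}: declared rate {declared_rate} Hz but time column implies "
            f"{inferred:.3f} Hz"
        )
    forces = df[FORCE_COLUMNS[1:]].to_numpy(dtype=float)
    return RawForceRecord(
        forces=forces,
        sampling_rate=inferred if declared_rate is None else float(declared_rate),
        geometry=geometry,
        **ids,
    )


def write_force_record(record: RawForceRecord, path: str | Path) -> Path:
    """Write a record in the canonical dialect; re-readable bit-identically.

    Forces are serialized with ``repr`` round-trip precision so a write →
    read cycle is the identity on the force array.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": record.times,
            "f1_N": record.forces[:, 0],
            "f2_N": record.forces[:, 1],
            "f3_N": record.forces[:, 2],
            "f4_N": record.forces[:, 3],
        }
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Session manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )


@dataclass(frozen=True)
class TrialEntry:
    subject_id: str
    phase: str            # baseline | pre | post
    direction: str        # AP | ML | MULTI
    repeat_index: int
    path: str


@dataclass
class SessionManifest:
    """Subjects plus the trial files recorded for each subject/phase."""

    subjects: list[SubjectRecord] = field(default_factory=list)
    trials: list[TrialEntry] = field(default_factory=list)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.subjects:
            sizes[s.group] = sizes.get(s.group, 0) + 1
        return sizes

    def trials_for(self, subject_id: str, phase: str | None = None) -> list[TrialEntry]:
        return [
            t
            for t in self.trials
            if t.subject_id == subject_id and (phase is None or t.phase == phase)
        ]


def read_manifest(path: str | Path, check_files: bool = True) -> SessionManifest:
    """Parse a YAML session manifest.

    Schema: ``subjects`` — list of {subject_id, group[, age, height_cm,
    weight_kg]}; ``trials`` — list of {subject_id, phase, direction,
    repeat_index, path}. Trial paths are resolved relative to the manifest.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise FormatError(f"{path}: manifest must be a mapping")
    subjects = [
        SubjectRecord(
            subject_id=str(s["subject_id"]),
            group=str(s["group"]),
            age=s.get("age"),
            height_cm=s.get("height_cm"),
            weight_kg=s.get("weight_kg"),
        )
        for s in data.get("subjects", [])
    ]
    trials = []
    for t in data.get("trials", []):
        trial_path = Path(t["path"])
        if not trial_path.is_absolute():
            trial_path = path.parent / trial_path
        if check_files and not trial_path.exists():
            raise ResolutionError(f"{path}: trial file not found: {trial_path}")
        trials.append(
            TrialEntry(
                subject_id=str(t["subject_id"]),
                phase=str(t["phase"]),
                direction=str(t["direction"]),
                repeat_index=int(t["repeat_index"]),
                path=str(trial_path),
            )
        )
    return SessionManifest(subjects=subjects, trials=trials)


def write_manifest(manifest: SessionManifest, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                **({"age": s.age} if s.age is not None else {}),
                **({"height_cm": s.height_cm} if s.height_cm is not None else {}),
                **({"weight_kg": s.weight_kg} if s.weight_kg is not None else {}),
            }
            for s in manifest.subjects
        ],
        "trials": [
            {
                "subject_id": t.subject_id,
                "phase": t.phase,
                "direction": t.direction,
                "repeat_index": t.repeat_index,
                "path": t.path,
            }
            for t in manifest.trials
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# Clinical outcome tables
# ---------------------------------------------------------------------------

OUTCOME_COLUMNS = ["subject_id", "phase", "bbs", "tug_s", "reach_cm"]


@dataclass
class OutcomeTable:
    """Per subject and phase: BBS score (points), TUG time (s), functional
    reach (cm). Validated against the scales' definitions on construction."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in OUTCOME_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"outcome table missing columns: {missing}")
        bbs = self.data["bbs"].to_numpy(dtype=float)
        if np.any((bbs < BBS_MIN) | (bbs > BBS_MAX)):
            bad = self.data.loc[(self.data.bbs < BBS_MIN) | (self.data.bbs > BBS_MAX)]
            raise RangeError(
                f"BBS outside 0-56 points for subject(s) {list(bad.subject_id)}"
            )
        tug = self.data["tug_s"].to_numpy(dtype=float)
        if np.any(tug <= 0):
            raise RangeError("TUG times must be positive")
        reach = self.data["reach_cm"].to_numpy(dtype=float)
        if np.any(reach < 0):
            raise RangeError("functional reach must be non-negative")

    def for_subject(self, subject_id: str, phase: str) -> pd.Series | None:
        sel = self.data[
            (self.data.subject_id == subject_id) & (self.data.phase == phase)
        ]
        return None if sel.empty else sel.iloc[0]


def read_outcomes(path: str | Path) -> OutcomeTable:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse outcome table ({exc})") from exc
    return OutcomeTable(df)


def write_outcomes(table: OutcomeTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False)
    return path
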