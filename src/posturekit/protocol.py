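"""Maximal-voluntary-excursion (MVE) assessment protocol.

Subjects stand with feet fixed 10 cm apart and shift their weight as far
as their limit of stability allows, without stepping. The protocol
records three consecutive excursion trials, tested twice per direction
(AP and ML), per subject and phase; a multi-directional "battery" trial
that visits all four directions in one recording is also supported
(direction label ``MULTI``).

The session layer turns raw force records into centered COP trajectories,
computes the per-trial metric battery, and aggregates: parameters are
computed for each trial and then averaged. The pooled (all-trial) average
is the headline per-subject value; per-direction sub-aggregates are kept
for calibrating the biofeedback game to the subject's own stability
limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .cop import COPTrajectory, center_trajectory, compute_cop
from .errors import ContractError, ParameterError
from .io import (
    OutcomeTable,
    RawForceRecord,
    SessionManifest,
    read_force_record,
)
from .metrics import SwayMetrics, aggregate_metrics, compute_all, metrics_table

DIRECTIONS = ("AP", "ML", "MULTI")

# Published screening cut-offs used to annotate reports.
TUG_FALL_RISK_S = 13.5          # slower than this flags elevated fall risk
BBS_CUTOFF_RANGE = (45.0, 51.0)  # below ~45-51 points flags impairment
REACH_RISK_RANGE_CM = (18.0, 22.0)  # shorter reach predicts fall risk


@dataclass
class Trial:
    direction: str
    repeat_index: int
    trajectory: COPTrajectory
    metrics: SwayMetrics


@dataclass
class MVESession:
    """All excursion trials of one subject in one phase, plus aggregates."""

    subject_id: str
    phase: str
    trials: list[Trial] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.trials:
            if t.direction not in DIRECTIONS:
                raise ParameterError(
                    f"direction must be one of {DIRECTIONS}, got {t.direction!r}"
                )

    def trials_in(self, direction: str) -> list[Trial]:
        return [t for t in self.trials if t.direction == direction]

    @property
    def aggregated(self) -> SwayMetrics:
        return aggregate(self)


def assemble_session(
    manifest: SessionManifest,
    records: Mapping[str, RawForceRecord] | None,
    subject_id: str,
    phase: str,
    config: RunConfig = DEFAULT_CONFIG,
    geometry=None,
) -> MVESession:
    """Build a session from manifest entries for one subject/phase.

    ``records`` maps trial file paths to already-loaded force records;
    entries absent from the mapping (or the mapping itself when ``None``)
    are read from disk, which requires ``geometry``. Trajectories are
    computed, centered per the configured origin method, and measured.
    A session missing a whole direction is still built, with a
    completeness warning recorded on it.
    """
    entries = manifest.trials_for(subject_id, phase)
    if not entries:
        raise ContractError(f"no trials for subject {subject_id!r} phase {phase!r}")
    per_direction: dict[tuple[str, int], int] = {}
    trials: list[Trial] = []
    for e in entries:
        key = (e.direction, e.repeat_index)
        per_direction[key] = per_direction.get(key, 0) + 1
    cap = config.mve.max_trials_per_direction
    counts: dict[str, int] = {}
    for e in entries:
        counts[e.direction] = counts.get(e.direction, 0) + 1
    for direction, n in counts.items():
        if direction != "MULTI" and n > cap:
            raise ContractError(
                f"{n} {direction} trials exceed the protocol cap of {cap}"
            )
    for e in entries:
        if records is not None and e.path in records:
            rec = records[e.path]
        else:
            if geometry is None:
                raise ParameterError(
                    "geometry required to read trial files from disk"
                )
            rec = read_force_record(
                e.path,
                geometry,
                subject_id=e.subject_id,
                direction_label=e.direction,
                phase_label=e.phase,
            )
        traj = compute_cop(rec, config)
        traj = center_trajectory(
            traj, reference=config.origin.method, window_s=config.origin.window_s
        )
        trials.append(
            Trial(
                direction=e.direction,
                repeat_index=e.repeat_index,
                trajectory=traj,
                metrics=compute_all(traj, config),
            )
        )
    session = MVESession(subject_id=subject_id, phase=phase, trials=trials)
    present = {t.direction for t in trials}
    if "MULTI" not in present:
        for d in ("AP", "ML"):
            if d not in present:
                session.warnings.append(f"incomplete session: no {d} trials")
    return session


def aggregate(session: MVESession) -> SwayMetrics:
    """Pooled field-wise mean of per-trial metrics across all trials."""
    if not session.trials:
        raise ContractError("cannot aggregate an empty session")
    return aggregate_metrics([t.metrics for t in session.trials])


def per_direction_aggregates(session: MVESession) -> dict[str, SwayMetrics]:
    """Sub-aggregates over trials sharing a direction label."""
    out: dict[str, SwayMetrics] = {}
    for d in DIRECTIONS:
        ts = session.trials_in(d)
        if ts:
            out[d] = aggregate_metrics([t.metrics for t in ts])
    return out


def directional_limits(session: MVESession) -> dict[str, float]:
    """Per-direction stability limits (mm) for game calibration.

    R/L come from trials that exercise the ML axis (ML or MULTI), A/P from
    trials that exercise the AP axis. Within those, only trials that
    actually targeted the direction contribute — a trial whose excursion
    toward a direction is under half the session's best toward it (e.g. a
    leftward trial's residual rightward sway) is excluded, since averaging
    it in would dilute the limit. The targeted trials' maxima are averaged.
    """
    if not session.trials:
        raise ContractError("cannot derive limits from an empty session")
    axis_trials = {
        "R": [t for t in session.trials if t.direction in ("ML", "MULTI")],
        "L": [t for t in session.trials if t.direction in ("ML", "MULTI")],
        "A": [t for t in session.trials if t.direction in ("AP", "MULTI")],
        "P": [t for t in session.trials if t.direction in ("AP", "MULTI")],
    }
    limits: dict[str, float] = {}
    for d, trials in axis_trials.items():
        if not trials:
            continue
        maxima = np.array([getattr(t.metrics, f"max_range_{d}") for t in trials])
        best = maxima.max()
        if best <= 0:
            limits[d] = 0.0
            continue
        targeted = maxima[maxima >= 0.5 * best]
        limits[d] = float(targeted.mean())
    return limits


def session_report(
    session: MVESession, outcomes: OutcomeTable | None = None
) -> dict:
    """Per-subject report: metrics table, per-direction aggregates, and
    clinical-scale annotations against published screening cut-offs."""
    agg = aggregate(session)
    rows = {"aggregate": agg}
    for d, m in per_direction_aggregates(session).items():
        rows[f"direction_{d}"] = m
    table = metrics_table(rows)
    report = {
        "subject_id": session.subject_id,
        "phase": session.phase,
        "n_trials": len(session.trials),
        "warnings": list(session.warnings),
        "metrics": agg.as_dict(table_names=True),
        "table": table,
        "clinical": {},
    }
    if outcomes is not None:
        row = outcomes.for_subject(session.subject_id, session.phase)
        if row is not None:
            flags = []
            if row.tug_s > TUG_FALL_RISK_S:
                flags.append(
                    f"TUG {row.tug_s:.2f} s exceeds {TUG_FALL_RISK_S} s: elevated fall risk"
                )
            if row.bbs < BBS_CUTOFF_RANGE[0]:
                flags.append(
                    f"BBS {row.bbs:.0f} below the {BBS_CUTOFF_RANGE[0]:.0f}-"
                    f"{BBS_CUTOFF_RANGE[1]:.0f} point cut-off range"
                )
            if row.reach_cm < REACH_RISK_RANGE_CM[0]:
                flags.append(
                    f"functional reach {row.reach_cm:.1f} cm below the "
                    f"{REACH_RISK_RANGE_CM[0]:.0f}-{REACH_RISK_RANGE_CM[1]:.0f} cm "
                    "risk-prediction range"
                )
            report["clinical"] = {
                "bbs": float(row.bbs),
                "tug_s": float(row.tug_s),
                "reach_cm": float(row.reach_cm),
                "flags": flags,
            }
    return report
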