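"""Finger-dynamics metrics: contact area, velocity, acceleration.

Stress raises muscle tension and motor-control variability in the wrist and
finger muscles, which shows up in the fingertip's contact patch and in the
kinematics of strokes.  Per stroke we summarise (i) the contact-ellipse area
computed from the logger's major/minor axes, and (ii) velocity and
acceleration obtained by finite-differencing the horizontal position.  All
strokes and substrokes of a trial contribute; trial values are the
unweighted mean of per-stroke values, trials aggregate to per-task-type
phase values (40 trials each), and the mixed-task level is the unweighted
mean of the three task-type values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .event_log import TASK_TYPES
from .stroke_segmentation import Stroke

METRIC_FIELDS = (
    "mean_area_mm2", "sd_area_mm2",
    "mean_velocity_mm_s", "sd_velocity_mm_s",
    "mean_accel_mm_s2", "sd_accel_mm_s2",
)


@dataclass(frozen=True)
class TrialMetrics:
    mean_area_mm2: float
    sd_area_mm2: float
    mean_velocity_mm_s: float
    sd_velocity_mm_s: float
    mean_accel_mm_s2: float
    sd_accel_mm_s2: float
    n_strokes_used: int

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in METRIC_FIELDS} | {
            "n_strokes_used": self.n_strokes_used}


def contact_area(major_mm, minor_mm, axes_are_full: bool = False):
    """Contact-patch area pi*a*b from the logger's ellipse axes.

    The axes are used literally as reported by the logger.  If they are full
    axes (diameters) the true ellipse area is pi*(a/2)*(b/2); pass
    ``axes_are_full=True`` to apply the /4 factor.
    """
    a = np.asarray(major_mm, dtype=float)
    b = np.asarray(minor_mm, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("ellipse axes must be non-negative")
    area = math.pi * a * b
    if axes_are_full:
        area = area / 4.0
    return area if area.ndim else float(area)


def stroke_kinematics(stroke: Stroke | pd.DataFrame):
    """First- and second-difference kinematics of the horizontal trajectory.

    v[i] = (x[i+1]-x[i]) / (t[i+1]-t[i]) at the n-1 interior steps, and the
    same finite difference of v gives the n-2 accelerations (signed; only the
    x-direction carries the task displacement).
    """
    ev = stroke.events if isinstance(stroke, Stroke) else stroke
    t = np.asarray(ev["t_s"], dtype=float)
    x = np.asarray(ev["x_mm"], dtype=float)
    if t.size < 3:
        raise ValueError("kinematics need at least 3 events")
    dt = np.diff(t)
    if np.any(dt < 0):
        raise ValueError("events must be time-sorted")
    if np.any(dt == 0):
        i = int(np.argmax(dt == 0))
        raise ValueError(f"duplicate timestamps at samples {i} and {i + 1} (t={t[i]})")
    v = np.diff(x) / dt
    t_mid = 0.5 * (t[:-1] + t[1:])
    a = np.diff(v) / np.diff(t_mid)
    return v, a


def _sd(values: np.ndarray) -> float:
    # sample SD where defined; a single observation has no spread
    return float(np.std(values, ddof=1)) if values.size >= 2 else 0.0


def trial_metrics(trial_strokes: Sequence[Stroke], axes_are_full: bool = False) -> TrialMetrics | None:
    """Per-trial metrics: mean of per-stroke summaries over all strokes/substrokes.

    Per stroke: mean/SD of contact area over every sample, and mean/SD of the
    signed velocity and acceleration series.  Strokes with fewer than 3
    events cannot support the acceleration difference and are skipped.
    Returns None (flagged-absent trial) when no stroke qualifies.
    """
    per_stroke = []
    for s in trial_strokes:
        if s.n_events < 3:
            continue
        area = contact_area(s.events["major_mm"], s.events["minor_mm"], axes_are_full)
        v, a = stroke_kinematics(s)
        per_stroke.append((
            float(np.mean(area)), _sd(np.asarray(area)),
            float(np.mean(v)), _sd(v),
            float(np.mean(a)), _sd(a),
        ))
    if not per_stroke:
        return None
    means = np.mean(np.asarray(per_stroke), axis=0)
    return TrialMetrics(*map(float, means), n_strokes_used=len(per_stroke))


def metrics_table(metrics_by_trial, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flatten {trial_id: TrialMetrics|None} into a DataFrame, optionally
    joined with trial annotations (task_type, condition, order)."""
    rows = []
    for trial_id, m in metrics_by_trial.items():
        row = {"trial_id": trial_id}
        row.update(m.as_dict() if m is not None else
                   {f: np.nan for f in METRIC_FIELDS} | {"n_strokes_used": 0})
        rows.append(row)
    df = pd.DataFrame(rows)
    if annotations is not None:
        df = df.merge(annotations, on="trial_id", how="left")
    return df


MIXED_TASK = "mixed_task"
PER_TASK_TYPE = "per_task_type"


def aggregate_phase(trials: pd.DataFrame, level: str = MIXED_TASK):
    """Aggregate one subject/condition's trial metrics to phase level.

    ``per_task_type``: the mean of each metric over that task type's valid
    trials (a Fitts-style block of 40).  ``mixed_task``: the unweighted mean
    of the three per-task-type values — not the pooled trial mean, so task
    types with different valid-trial counts carry equal weight.

    Returns a DataFrame indexed by task_type (per_task_type) or a Series
    (mixed_task).
    """
    valid = trials[trials["n_strokes_used"] > 0]
    per_task = valid.groupby("task_type")[list(METRIC_FIELDS)].mean()
    missing = [t for t in TASK_TYPES if t not in per_task.index or
               per_task.loc[t].isna().any()]
    if missing:
        raise ValueError(f"no valid trials for task type(s) {missing}; "
                         "cannot form phase aggregate")
    per_task = per_task.loc[list(TASK_TYPES)]
    if level == PER_TASK_TYPE:
        return per_task
    if level == MIXED_TASK:
        return per_task.mean(axis=0)
    raise ValueError(f"unknown aggregation level {level!r}")
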