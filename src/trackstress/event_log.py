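"""Multi-touch event-log and trial-annotation formats.

The trackpad logger records one row per touch sample: timestamp, finger id,
x/y position (hundredth-millimetre resolution on a 140x70 mm pad), the major
and minor axes of the contact ellipse, the interaction state and the pressed
flag.  Trials are described separately by annotation rows carrying the task
metadata (task type, distance D and width W in pixels) and the trial's time
window.  Both tables are serialised as plain RFC-4180 CSV so that logs from
any capture tool can be converted into the dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger("trackstress")

PAD_X_MM = 140.0
PAD_Y_MM = 70.0

EVENT_COLUMNS = [
    "t_s", "finger_id", "x_mm", "y_mm", "major_mm", "minor_mm", "state", "pressed",
]
ANNOTATION_COLUMNS = [
    "trial_id", "subject_id", "phase", "condition", "task_type",
    "distance_px", "width_px", "t_start_s", "t_end_s",
]

TOUCH_STATES = ("touching", "dragging", "lifted")
PHASES = ("Relaxation", "tRelaxed", "Stressor", "tStressed")

# Table of valid task geometry (pixels): 5 distances x 4 widths per task type.
TASK_DISTANCES_PX = (64, 128, 256, 512, 1024)
TASK_WIDTHS_PX = {
    "click": (8, 16, 32, 64),
    "drag_and_drop": (16, 32, 64, 128),
    "steer": (8, 16, 32, 64),
}
TASK_TYPES = tuple(TASK_WIDTHS_PX)


class EventLogError(ValueError):
    """Raised when an event log or annotation table violates the dialect."""


class TouchEvent(NamedTuple):
    """A single logger sample (convenience record; bulk data lives in DataFrames)."""

    t_s: float
    finger_id: int
    x_mm: float
    y_mm: float
    major_mm: float
    minor_mm: float
    state: str = "touching"
    pressed: bool = True


@dataclass(frozen=True)
class TrialAnnotation:
    trial_id: str
    subject_id: str
    phase: str
    condition: str
    task_type: str
    distance_px: int
    width_px: int
    t_start_s: float
    t_end_s: float

    def validate(self) -> None:
        if not self.t_start_s < self.t_end_s:
            raise EventLogError(
                f"trial {self.trial_id}: t_start {self.t_start_s} >= t_end {self.t_end_s}")
        if self.task_type not in TASK_TYPES:
            raise EventLogError(f"trial {self.trial_id}: unknown task_type {self.task_type}")
        if self.distance_px not in TASK_DISTANCES_PX:
            raise EventLogError(f"trial {self.trial_id}: invalid distance {self.distance_px}")
        if self.width_px not in TASK_WIDTHS_PX[self.task_type]:
            raise EventLogError(
                f"trial {self.trial_id}: width {self.width_px} invalid for {self.task_type}")


def events_frame(events) -> pd.DataFrame:
    """Coerce a sequence of TouchEvents (or a DataFrame) to the canonical frame."""
    if isinstance(events, pd.DataFrame):
        df = events.loc[:, EVENT_COLUMNS].copy()
    else:
        df = pd.DataFrame(list(events), columns=EVENT_COLUMNS)
    df["t_s"] = df["t_s"].astype(float)
    df["finger_id"] = df["finger_id"].astype(int)
    for c in ("x_mm", "y_mm", "major_mm", "minor_mm"):
        df[c] = df[c].astype(float)
    df["state"] = df["state"].astype(str)
    df["pressed"] = df["pressed"].astype(bool)
    return df


def annotations_frame(annotations) -> pd.DataFrame:
    if isinstance(annotations, pd.DataFrame):
        df = annotations.loc[:, ANNOTATION_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [a.__dict__ if isinstance(a, TrialAnnotation) else a for a in annotations],
            columns=ANNOTATION_COLUMNS,
        )
    df["distance_px"] = df["distance_px"].astype(int)
    df["width_px"] = df["width_px"].astype(int)
    df["t_start_s"] = df["t_start_s"].astype(float)
    df["t_end_s"] = df["t_end_s"].astype(float)
    return df


def validate_events(df: pd.DataFrame) -> None:
    """Check TouchEvent invariants; raise listing the offending row numbers."""
    bad: list[str] = []

    def flag(mask: pd.Series, why: str) -> None:
        rows = np.flatnonzero(np.asarray(mask))
        if rows.size:
            shown = ", ".join(map(str, rows[:10]))
            more = "" if rows.size <= 10 else f" (+{rows.size - 10} more)"
            bad.append(f"{why}: rows {shown}{more}")

    flag(~np.isfinite(df["t_s"]), "non-finite t_s")
    flag(df["minor_mm"] < 0, "negative minor axis")
    flag(df["major_mm"] < df["minor_mm"], "major axis < minor axis")
    flag((df["x_mm"] < 0) | (df["x_mm"] > PAD_X_MM), f"x outside 0-{PAD_X_MM} mm")
    flag((df["y_mm"] < 0) | (df["y_mm"] > PAD_Y_MM), f"y outside 0-{PAD_Y_MM} mm")
    flag(~df["state"].isin(TOUCH_STATES), "unknown state")
    # time monotone (non-decreasing) within each finger trace
    for fid, grp in df.groupby("finger_id", sort=False):
        dt = grp["t_s"].diff()
        rows = grp.index[np.asarray(dt < 0)]
        if len(rows):
            bad.append(f"non-monotone t_s for finger {fid}: rows {list(rows[:10])}")
    if bad:
        raise EventLogError("invalid event log: " + "; ".join(bad))


def write_event_log(events, annotations, events_path, annotations_path) -> None:
    """Serialise events and annotations as CSV.

    Coordinates and axes are written with exactly 2 decimals (the logger's
    hundredth-millimetre resolution), times with 6; the files round-trip
    losslessly at that precision.
    """
    ev = events_frame(events)
    validate_events(ev)
    ann = annotations_frame(annotations)
    out = ev.copy()
    out["t_s"] = out["t_s"].map(lambda v: f"{v:.6f}")
    for c in ("x_mm", "y_mm", "major_mm", "minor_mm"):
        out[c] = out[c].map(lambda v: f"{v:.2f}")
    out["pressed"] = out["pressed"].map(lambda v: "true" if v else "false")
    out.to_csv(events_path, index=False)
    aout = ann.copy()
    for c in ("t_start_s", "t_end_s"):
        aout[c] = aout[c].map(lambda v: f"{v:.6f}")
    aout.to_csv(annotations_path, index=False)


def read_event_log(events_path, annotations_path=None):
    """Read an event log (and optionally annotations) back into typed frames."""
    ev = pd.read_csv(
        events_path,
        dtype={"finger_id": int, "state": str},
        converters={"pressed": lambda s: s in ("true", "True", "1")},
    )
    if list(ev.columns) != EVENT_COLUMNS:
        raise EventLogError(
            f"unexpected event columns {list(ev.columns)}; expected {EVENT_COLUMNS}")
    ev = events_frame(ev)
    validate_events(ev)
    if annotations_path is None:
        return ev, None
    ann = pd.read_csv(annotations_path)
    if list(ann.columns) != ANNOTATION_COLUMNS:
        raise EventLogError(
            f"unexpected annotation columns {list(ann.columns)}; expected {ANNOTATION_COLUMNS}")
    ann = annotations_frame(ann)
    for row in ann.itertuples(index=False):
        TrialAnnotation(**row._asdict()).validate()
    return ev, ann


class TrialAssignment(NamedTuple):
    by_trial: Mapping[str, pd.DataFrame]
    n_unassigned: int


def assign_events_to_trials(events, annotations) -> TrialAssignment:
    """Assign each event to the trial whose half-open [t_start, t_end) window holds it.

    Events outside every window are dropped (their count is reported and
    logged).  Overlapping trial windows are an error: the mapping would be
    ambiguous.
    """
    ev = events_frame(events)
    ann = annotations_frame(annotations).sort_values("t_start_s").reset_index(drop=True)
    starts = ann["t_start_s"].to_numpy()
    ends = ann["t_end_s"].to_numpy()
    if np.any(ends[:-1] > starts[1:]):
        i = int(np.argmax(ends[:-1] > starts[1:]))
        raise EventLogError(
            f"overlapping trial windows: {ann['trial_id'][i]} ends after "
            f"{ann['trial_id'][i + 1]} starts")
    t = ev["t_s"].to_numpy()
    idx = np.searchsorted(starts, t, side="right") - 1
    inside = (idx >= 0) & (t < ends[np.clip(idx, 0, len(ends) - 1)])
    n_unassigned = int((~inside).sum())
    if n_unassigned:
        logger.warning("%d events fall outside all trial windows; dropped", n_unassigned)
    by_trial: dict[str, pd.DataFrame] = {}
    ev_in = ev[inside]
    for i, grp in ev_in.groupby(idx[inside], sort=True):
        by_trial[str(ann["trial_id"].iloc[int(i)])] = grp.reset_index(drop=True)
    return TrialAssignment(by_trial, n_unassigned)
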