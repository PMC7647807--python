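"""Stroke segmentation: split a trial's touch samples into continuous strokes.

Trackpad users lift fingers, switch fingers or use two hands mid-trial, so a
single trial's log often contains several disjoint (sometimes concurrent)
traces.  A *stroke* is a maximal contiguous run of samples from one finger
with no large time gap and no large coordinate jump between consecutive
samples.  Downstream, the mass-spring-damper fit uses only the largest
continuous stroke (greatest net horizontal extent); the finger-dynamics
metrics keep every stroke and substroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .event_log import events_frame


@dataclass(frozen=True)
class SegmentationConfig:
    """Cut thresholds.  A cut is made between consecutive same-finger samples
    whenever the time gap exceeds ``max_gap_ms`` or either coordinate jumps by
    more than ``max_jump_mm``; fragments shorter than ``min_stroke_samples``
    are discarded (but counted)."""

    max_gap_ms: float = 50.0      # ~6x the logger's mean sampling interval
    max_jump_mm: float = 15.0     # above the fastest per-sample displacement
    min_stroke_samples: int = 4

    def __post_init__(self) -> None:
        if not (self.max_gap_ms > 0 and self.max_jump_mm > 0 and self.min_stroke_samples > 0):
            raise ValueError("segmentation thresholds must be positive")


@dataclass(frozen=True)
class Stroke:
    """One contiguous single-finger trace."""

    finger_id: int
    events: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.events) < 2:
            raise ValueError("a stroke needs at least 2 events")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def t_start(self) -> float:
        return float(self.events["t_s"].iloc[0])

    @property
    def t_span(self) -> float:
        return float(self.events["t_s"].iloc[-1] - self.events["t_s"].iloc[0])

    @property
    def x_extent_mm(self) -> float:
        """Net horizontal displacement |x_end - x_start|."""
        return float(abs(self.events["x_mm"].iloc[-1] - self.events["x_mm"].iloc[0]))


@dataclass(frozen=True)
class SegmentationResult:
    strokes: tuple[Stroke, ...]
    n_discarded_fragments: int
    n_discarded_events: int

    @property
    def n_retained_events(self) -> int:
        return sum(s.n_events for s in self.strokes)

    @property
    def has_gap(self) -> bool:
        """A trial has a gap if its events did not form one clean stroke."""
        return len(self.strokes) > 1 or self.n_discarded_fragments > 0


def split_strokes(trial_events, config: SegmentationConfig = SegmentationConfig()) -> SegmentationResult:
    """Partition a trial's events into strokes.

    Events are grouped by finger id (concurrent fingers give separate,
    possibly time-overlapping strokes), then each finger's trace is cut at
    every threshold violation.  Empty input yields an empty result.
    """
    ev = events_frame(trial_events) if len(trial_events) else None
    if ev is None or ev.empty:
        return SegmentationResult((), 0, 0)
    strokes: list[Stroke] = []
    n_frag = 0
    n_disc = 0
    max_gap_s = config.max_gap_ms / 1000.0
    for fid, grp in ev.groupby("finger_id", sort=True):
        grp = grp.sort_values("t_s", kind="stable").reset_index(drop=True)
        t = grp["t_s"].to_numpy()
        x = grp["x_mm"].to_numpy()
        y = grp["y_mm"].to_numpy()
        cut = (
            (np.diff(t) > max_gap_s)
            | (np.abs(np.diff(x)) > config.max_jump_mm)
            | (np.abs(np.diff(y)) > config.max_jump_mm)
        )
        bounds = np.concatenate(([0], np.flatnonzero(cut) + 1, [len(grp)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = grp.iloc[int(lo):int(hi)].reset_index(drop=True)
            if len(seg) < config.min_stroke_samples:
                n_frag += 1
                n_disc += len(seg)
            else:
                strokes.append(Stroke(int(fid), seg))
    strokes.sort(key=lambda s: (s.t_start, s.finger_id))
    return SegmentationResult(tuple(strokes), n_frag, n_disc)


def select_largest_stroke(strokes: Sequence[Stroke]) -> Stroke:
    """The stroke with the greatest net x-extent (the trial's main movement).

    Ties go to the longer time span, then to the earlier start, so selection
    is deterministic.
    """
    if not strokes:
        raise ValueError("no valid stroke")
    return max(strokes, key=lambda s: (s.x_extent_mm, s.t_span, -s.t_start))


def gap_statistics(results: Mapping[object, SegmentationResult] | Iterable[SegmentationResult]) -> float:
    """Fraction of trials with at least one gap (more than one stroke, or any
    discarded fragment)."""
    values = list(results.values()) if isinstance(results, Mapping) else list(results)
    if not values:
        raise ValueError("gap_statistics requires at least one trial")
    return float(np.mean([r.has_gap for r in values]))
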