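"""Electrodermal-activity (EDA) processing for stressor validation.

Skin conductance (µS) from a wrist-worn sensor is screened for quality,
low-pass filtered, decomposed into a slow *tonic* baseline plus the fast
*phasic* component, and summarised per experimental phase as tonic mean,
phasic mean, and the count of skin-conductance responses (SCRs — phasic
peaks above 0.01 µS).  Elevated tonic level, phasic activity and SCR rate
index sympathetic arousal and validate that a stressor worked.

The tonic/phasic split here is a deterministic sliding-window
low-percentile baseline (10th percentile over 10 s, then 1 s mean
smoothing).  It is a simple, dependency-free decomposition, not a
deconvolution of sudomotor-nerve activity; absolute tonic/phasic values are
therefore comparable only within this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

SCR_MIN_AMPLITUDE_US = 0.01
SCR_MIN_SEPARATION_S = 1.0

NO_SIGNAL = "no_signal"
ABOVE_20US = "above_20uS"
NOISY_EPOCHS = "noisy_epochs_gt_5pct"


@dataclass(frozen=True)
class EDASeries:
    """Uniformly sampled skin-conductance series."""

    t_s: np.ndarray = field(repr=False)
    eda_uS: np.ndarray = field(repr=False)
    sample_rate_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        y = np.asarray(self.eda_uS, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t_s and eda_uS must be 1-D arrays of equal length")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "eda_uS", y)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.t_s)

    def replace_values(self, values: np.ndarray) -> "EDASeries":
        return EDASeries(self.t_s, np.asarray(values, dtype=float), self.sample_rate_hz)


@dataclass(frozen=True)
class EDAQualityReport:
    excluded: bool
    reasons: frozenset[str]
    noisy_epoch_fraction: float

    def __post_init__(self) -> None:
        assert self.excluded == bool(self.reasons)


def filter_eda(series: EDASeries, cutoff_hz: float = 1.0, order: int = 6) -> EDASeries:
    """Zero-phase 6th-order Butterworth low-pass at 1 Hz.

    Forward-backward (``sosfiltfilt``) application avoids shifting SCR peak
    latencies; length is preserved.
    """
    if series.sample_rate_hz <= 2 * cutoff_hz:
        raise ValueError(
            f"sample rate {series.sample_rate_hz} Hz must exceed twice the "
            f"{cutoff_hz} Hz cutoff")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=series.sample_rate_hz, output="sos")
    return series.replace_values(signal.sosfiltfilt(sos, series.eda_uS))


def screen_quality(series: EDASeries, epoch_s: float = 5.0,
                   max_noisy_fraction: float = 0.05,
                   max_jump_uS: float = 1.0,
                   valid_range_uS: tuple[float, float] = (0.01, 20.0)) -> EDAQualityReport:
    """Rule-based recording-quality screen.

    Exclusion reasons: a flat signal (range < 0.01 µS, e.g. loose contact),
    any sample above 20 µS (anomalous conductance), or more than 5% noisy
    5-second epochs.  An epoch is noisy when any sample-to-sample jump
    exceeds 1 µS or any value leaves [0.01, 20] µS — a deterministic
    stand-in for classifier-based artifact detection, with all thresholds
    configurable.
    """
    y = series.eda_uS
    if len(y) < 1:
        raise ValueError("screen_quality needs at least one epoch of data")
    reasons: set[str] = set()
    if float(np.ptp(y)) < 0.01:
        reasons.add(NO_SIGNAL)
    if np.any(y > valid_range_uS[1]):
        reasons.add(ABOVE_20US)
    n_per = max(1, int(round(epoch_s * series.sample_rate_hz)))
    n_epochs = max(1, len(y) // n_per)
    noisy = 0
    for i in range(n_epochs):
        seg = y[i * n_per:(i + 1) * n_per]
        if np.any(np.abs(np.diff(seg)) > max_jump_uS) or \
           np.any((seg < valid_range_uS[0]) | (seg > valid_range_uS[1])):
            noisy += 1
    frac = noisy / n_epochs
    if frac > max_noisy_fraction:
        reasons.add(NOISY_EPOCHS)
    return EDAQualityReport(bool(reasons), frozenset(reasons), frac)


def decompose_eda(series: EDASeries, window_s: float = 10.0,
                  percentile: float = 10.0, smooth_s: float = 1.0):
    """Split a (filtered) series into tonic baseline and phasic component.

    Tonic: centred sliding-window ``percentile`` (default 10th over 10 s),
    then a centred ``smooth_s`` moving-average.  Phasic: series − tonic,
    floored at zero.  The unfloored phasic plus tonic reconstructs the input
    exactly, and the baseline is offset-equivariant (adding a constant moves
    tonic, not phasic).

    Returns ``(tonic, phasic)`` arrays.
    """
    y = series.eda_uS
    w = int(round(window_s * series.sample_rate_hz))
    if len(y) < w:
        raise ValueError(f"series of {len(y)} samples shorter than the "
                         f"{window_s} s ({w}-sample) baseline window")
    s = pd.Series(y)
    tonic = s.rolling(w, center=True, min_periods=1).quantile(percentile / 100.0)
    m = max(1, int(round(smooth_s * series.sample_rate_hz)))
    tonic = tonic.rolling(m, center=True, min_periods=1).mean().to_numpy()
    phasic = np.maximum(y - tonic, 0.0)
    return tonic, phasic


def count_scrs(phasic: np.ndarray, sample_rate_hz: float,
               min_amplitude_uS: float = SCR_MIN_AMPLITUDE_US,
               min_separation_s: float = SCR_MIN_SEPARATION_S):
    """Count SCR peaks: local maxima of the phasic signal with prominence of
    at least ``min_amplitude_uS`` and at least ``min_separation_s`` apart.

    Returns ``(count, peak_indices)``.
    """
    phasic = np.asarray(phasic, dtype=float)
    distance = max(1, int(round(min_separation_s * sample_rate_hz)))
    peaks, _ = signal.find_peaks(phasic, prominence=min_amplitude_uS, distance=distance)
    return len(peaks), peaks


@dataclass(frozen=True)
class PhaseEDASummary:
    phase: str
    tonic_mean_uS: float
    phasic_mean_uS: float
    scr_count: int


TASK_PHASES = ("tRelaxed", "tStressed")


def eda_phase_summary(series: EDASeries, phase_windows: Mapping[str, tuple[float, float]],
                      min_amplitude_uS: float = SCR_MIN_AMPLITUDE_US) -> pd.DataFrame:
    """Per-phase EDA summary (task phases only).

    ``phase_windows`` maps phase name to a [t_start, t_end) window in the
    series' time base.  The series is filtered and decomposed once; SCR
    peaks are detected globally and assigned to windows by time, so counts
    are additive over disjoint subwindows.
    """
    for phase in TASK_PHASES:
        if phase not in phase_windows:
            raise ValueError(f"missing phase window for {phase}")
    filt = filter_eda(series)
    tonic, phasic = decompose_eda(filt)
    _, peaks = count_scrs(phasic, series.sample_rate_hz, min_amplitude_uS)
    peak_t = series.t_s[peaks]
    rows = []
    for phase in TASK_PHASES:
        t0, t1 = phase_windows[phase]
        mask = (series.t_s >= t0) & (series.t_s < t1)
        if not mask.any():
            raise ValueError(f"phase window {phase} [{t0}, {t1}) contains no samples")
        rows.append(PhaseEDASummary(
            phase,
            float(np.mean(tonic[mask])),
            float(np.mean(phasic[mask])),
            int(np.sum((peak_t >= t0) & (peak_t < t1))),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
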