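"""Mass-spring-damper identification of pointing strokes via AR(2)/LPC fits.

A goal-directed stroke toward a target approximates the step response of a
single-degree-of-freedom mass-spring-damper system.  For an underdamped
system with damping ratio Gamma in (0,1) and damped frequency omega (rad/s)

    x(t) = D * [1 - e^(-Gamma*wn*t) (cos(omega*t) + (Gamma*wn/omega) sin(omega*t))],
    wn = omega / sqrt(1 - Gamma^2),

so after subtracting the steady-state level D the residual is a decaying
sinusoid — exactly the impulse response of a second-order autoregressive
(AR(2)) process.  Fitting  x[n] = a1 x[n-1] + a2 x[n-2] + e[n]  by least
squares (the covariance / linear-predictive-coding method) yields a complex
pole pair  z = r e^(+-i theta);  mapping to continuous time via
s = (ln r +- i theta)/dt  gives

    Gamma = -Re(s)/|s|,    omega = |Im(s)| = theta/dt,    wn = |s|.

Real poles mean the fitted motion is not oscillatory (overdamped); such
trials are flagged and excluded from aggregation rather than forced into the
underdamped parameterisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stroke_segmentation import (
    SegmentationConfig,
    Stroke,
    select_largest_stroke,
    split_strokes,
)

DEFAULT_GRID_MS = 10.0

UNDERDAMPED = "underdamped"
OVERDAMPED_FLAGGED = "overdamped_flagged"


class StrokeTooShortError(ValueError):
    pass


@dataclass(frozen=True)
class AR2Fit:
    a1: float
    a2: float
    residual_rms: float
    poles: tuple[complex, complex]


@dataclass(frozen=True)
class MSDParams:
    """Second-order model summary of one stroke.

    ``damping_ratio_gamma``/``damped_frequency_omega`` are None when the fit
    is overdamped (real poles).  ``unstable`` marks non-decaying fits
    (|pole| >= 1), which are excluded from aggregation like overdamped ones.
    """

    damping_ratio_gamma: float | None
    damped_frequency_omega: float | None  # rad/s
    natural_frequency: float | None       # rad/s
    regime: str
    unstable: bool = False
    residual_rms: float = float("nan")
    n_samples_used: int = 0

    @property
    def usable(self) -> bool:
        return self.regime == UNDERDAMPED and not self.unstable


def step_response(t, distance, zeta, omega_d):
    """Closed-form underdamped step response (the generator/analysis ground truth)."""
    t = np.asarray(t, dtype=float)
    if not 0.0 < zeta < 1.0:
        raise ValueError("step_response requires an underdamped system (0 < zeta < 1)")
    if omega_d <= 0:
        raise ValueError("omega_d must be positive")
    wn = omega_d / math.sqrt(1.0 - zeta * zeta)
    env = np.exp(-zeta * wn * t)
    return distance * (1.0 - env * (np.cos(omega_d * t) + (zeta * wn / omega_d) * np.sin(omega_d * t)))


def preprocess_stroke(stroke: Stroke | pd.DataFrame, grid_ms: float = DEFAULT_GRID_MS,
                      tail_cutoff_frac: float = 0.02):
    """Resample a stroke's x-trajectory onto a uniform grid and remove the
    steady-state level.

    Linear interpolation onto a ``grid_ms`` grid starting at the stroke's
    first sample; the steady-state level is estimated as the mean of the
    final 10% of grid samples (at least one) and subtracted, so that for an
    ideal step response the residual is exactly the decaying sinusoid.

    The residual is then truncated after the last sample whose magnitude
    reaches ``tail_cutoff_frac`` of its peak: once the oscillation has
    decayed into the measurement noise the remaining samples carry no
    dynamics and would only bias the autoregressive fit (noisy regressors
    attenuate the estimated poles).  On an exact noise-free response any
    trailing subsegment still satisfies the same recurrence, so truncation
    never changes the exact-recovery result.

    Returns ``(t_grid, x_detrended)``.
    """
    ev = stroke.events if isinstance(stroke, Stroke) else stroke
    t = np.asarray(ev["t_s"], dtype=float)
    x = np.asarray(ev["x_mm"], dtype=float)
    dt = grid_ms / 1000.0
    duration = t[-1] - t[0]
    if duration < 3 * dt:
        raise StrokeTooShortError(
            f"stroke spans {duration * 1000:.1f} ms < 3 grid steps of {grid_ms} ms")
    n = int(math.floor(duration / dt)) + 1
    t_grid = t[0] + dt * np.arange(n)
    x_grid = np.interp(t_grid, t, x)
    n_tail = max(1, int(round(0.1 * n)))
    steady = float(np.mean(x_grid[-n_tail:]))
    resid = x_grid - steady
    if tail_cutoff_frac > 0:
        peak = float(np.max(np.abs(resid)))
        if peak > 0:
            above = np.flatnonzero(np.abs(resid) >= tail_cutoff_frac * peak)
            keep = max(int(above[-1]) + 1, min(8, n))
            t_grid, resid = t_grid[:keep], resid[:keep]
    return t_grid, resid


def fit_ar2(series: Sequence[float]) -> AR2Fit:
    """Least-squares (covariance-method) AR(2) fit of a uniform series.

    Minimises the one-step-ahead prediction error of
    ``x[n] = a1 x[n-1] + a2 x[n-2]`` over n = 2..N-1.  Exact on noiseless
    second-order recurrences, unlike the autocorrelation (windowed) method.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError(f"fit_ar2 needs >= 8 samples, got {x.size}")
    X = np.column_stack([x[1:-1], x[:-2]])
    y = x[2:]
    scale = float(np.max(np.abs(X)))
    if scale == 0.0 or np.linalg.matrix_rank(X / scale, tol=1e-12) < 2:
        raise ValueError("rank-deficient AR(2) design (constant or degenerate series)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a1, a2 = (float(coef[0]), float(coef[1]))
    resid = y - X @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    roots = np.roots([1.0, -a1, -a2])
    return AR2Fit(a1, a2, rms, (complex(roots[0]), complex(roots[1])))


def ar2_to_msd(fit: AR2Fit, dt_s: float) -> MSDParams:
    """Map AR(2) poles to continuous-time damping ratio and damped frequency.

    Complex pole pair z = r e^(+-i theta) -> s = (ln r + i theta)/dt, then
    Gamma = -Re(s)/|s| and omega = theta/dt.  Real poles are flagged
    overdamped; |z| >= 1 is flagged unstable (no decay).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    z = fit.poles[0]
    if abs(z.imag) < 1e-12 or abs(fit.poles[1].imag) < 1e-12:
        return MSDParams(None, None, None, OVERDAMPED_FLAGGED, residual_rms=fit.residual_rms)
    r = abs(z)
    theta = abs(math.atan2(z.imag, z.real))
    unstable = r >= 1.0
    s = complex(math.log(r) / dt_s, theta / dt_s)
    mag = abs(s)
    gamma = -s.real / mag if mag > 0 else 0.0
    omega = theta / dt_s
    return MSDParams(gamma, omega, mag, UNDERDAMPED, unstable=unstable,
                     residual_rms=fit.residual_rms)


def estimate_stroke_msd(stroke: Stroke, grid_ms: float = DEFAULT_GRID_MS) -> MSDParams:
    t_grid, x = preprocess_stroke(stroke, grid_ms)
    fit = fit_ar2(x)
    params = ar2_to_msd(fit, grid_ms / 1000.0)
    return MSDParams(
        params.damping_ratio_gamma, params.damped_frequency_omega,
        params.natural_frequency, params.regime, params.unstable,
        params.residual_rms, n_samples_used=len(x),
    )


def estimate_trial_msd(trial_events, seg_config: SegmentationConfig = SegmentationConfig(),
                       grid_ms: float = DEFAULT_GRID_MS) -> MSDParams | None:
    """Full per-trial pipeline: segment, take the largest stroke, fit, map.

    Returns None (flagged absent) when the trial has no usable stroke, the
    largest stroke is too short, or the fit degenerates — batch callers count
    these rather than aborting.
    """
    seg = split_strokes(trial_events, seg_config)
    if not seg.strokes:
        return None
    stroke = select_largest_stroke(seg.strokes)
    try:
        return estimate_stroke_msd(stroke, grid_ms)
    except (StrokeTooShortError, ValueError):
        return None


def estimate_msd_batch(events_by_trial, seg_config: SegmentationConfig = SegmentationConfig(),
                       grid_ms: float = DEFAULT_GRID_MS) -> pd.DataFrame:
    """Per-trial MSD table: trial_id, gamma, omega_rad_s, regime, residual_rms,
    n_samples_used.  Flagged/absent trials get regime='flagged_absent'."""
    rows = []
    for trial_id, ev in events_by_trial.items():
        p = estimate_trial_msd(ev, seg_config, grid_ms)
        if p is None:
            rows.append(dict(trial_id=trial_id, gamma=np.nan, omega_rad_s=np.nan,
                             regime="flagged_absent", residual_rms=np.nan, n_samples_used=0))
        else:
            usable = p.usable
            rows.append(dict(
                trial_id=trial_id,
                gamma=p.damping_ratio_gamma if usable else np.nan,
                omega_rad_s=p.damped_frequency_omega if usable else np.nan,
                regime=p.regime if not p.unstable else "unstable",
                residual_rms=p.residual_rms,
                n_samples_used=p.n_samples_used,
            ))
    return pd.DataFrame(rows, columns=["trial_id", "gamma", "omega_rad_s", "regime",
                                       "residual_rms", "n_samples_used"])
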