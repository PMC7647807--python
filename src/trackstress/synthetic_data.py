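"""Synthetic trackpad-study generator with known ground truth.

Real subject data for this kind of study are rarely released, so every
downstream stage is exercised against simulated studies whose generating
parameters are known exactly: Fitts-style task schedules (click / steer /
drag-and-drop blocks over a 5x4 distance-by-width grid, two repetitions
each), touch logs whose x-trajectories follow the underdamped
mass-spring-damper step response the analysis fits, contact-ellipse axes
drawn so the ellipse area has the configured per-condition mean and spread,
multi-finger gap artifacts at a configurable per-trial probability,
self-report marker values, and electrodermal activity built as tonic drift
plus biexponential skin-conductance-response pulses.

Defaults emulate the study conditions the analysis assumes: 18 subjects in
two counterbalanced arms (8 Relax-Stress / 10 Stress-Relax), 120 trials per
condition, sampling intervals with mean 8.17 ms (SD 3.75), a 38% per-trial
gap rate, raw click contact areas around 270.9 (relaxed) vs 284.6 mm^2
(stressed) with within-trial SDs 16.7 vs 21.2, and EDA tonic levels around
2.1 vs 4.2 uS with SCR rates rising under stress.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .eda_processing import EDASeries
from .event_log import (
    EVENT_COLUMNS,
    TASK_DISTANCES_PX,
    TASK_TYPES,
    TASK_WIDTHS_PX,
    TrialAnnotation,
)
from .msd_model import step_response

CONDITIONS = ("tRelaxed", "tStressed")
ARMS = ("Relax-Stress", "Stress-Relax")

# Self-report markers SR0..SR5 bracket the phases; per-arm mapping of each
# phase to its (before, after) markers.  The stressed-task phase of the
# Relax-Stress arm is bracketed by SR4 and SR5.
SR_MARKERS = tuple(f"SR{i}" for i in range(6))
SR_PHASE_MARKERS: dict[str, dict[str, tuple[str, str]]] = {
    "Relax-Stress": {
        "Relaxation": ("SR0", "SR1"),
        "tRelaxed": ("SR1", "SR2"),
        "Stressor": ("SR3", "SR4"),
        "tStressed": ("SR4", "SR5"),
    },
    "Stress-Relax": {
        "Stressor": ("SR0", "SR1"),
        "tStressed": ("SR1", "SR2"),
        "Relaxation": ("SR3", "SR4"),
        "tRelaxed": ("SR4", "SR5"),
    },
}

# rng stream tags so every random decision has its own reproducible stream
_STREAM_BLOCK, _STREAM_CONFIG, _STREAM_AREA, _STREAM_STROKE = 1, 2, 3, 4
_STREAM_ARTIFACT, _STREAM_EDA, _STREAM_SR, _STREAM_AREA_SD = 5, 6, 7, 8


def _key(name: str) -> int:
    return zlib.crc32(name.encode())


@dataclass(frozen=True)
class TaskConfig:
    task_type: str
    distance_px: int
    width_px: int

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task type {self.task_type}")
        if self.distance_px not in TASK_DISTANCES_PX:
            raise ValueError(f"invalid distance {self.distance_px}")
        if self.width_px not in TASK_WIDTHS_PX[self.task_type]:
            raise ValueError(f"invalid width {self.width_px} for {self.task_type}")


@dataclass(frozen=True)
class TrialSpec:
    trial_id: str
    subject_id: str
    condition: str
    task_config: TaskConfig
    repetition: int
    order_index: int


@dataclass(frozen=True)
class MSDTruth:
    """Ground-truth underdamped dynamics: damping ratio and damped frequency."""

    zeta: float
    omega_d_rad_s: float

    def __post_init__(self) -> None:
        if not 0.0 < self.zeta < 1.0:
            raise ValueError("zeta must be in (0, 1): only underdamped strokes are emitted")
        if self.omega_d_rad_s <= 0:
            raise ValueError("omega_d must be positive")

    @property
    def omega_n(self) -> float:
        return self.omega_d_rad_s / math.sqrt(1.0 - self.zeta**2)


@dataclass(frozen=True)
class AreaModel:
    """Contact-area structure (mm^2, treating pi*a*b literally).

    Per-condition within-trial SDs are the sample-to-sample spread inside a
    stroke; between_subject_sd is the spread of subjects' condition-level
    means; condition_noise_sd is the subject-by-condition deviation that
    gives paired differences a nonzero variance; trial_level_sd jitters each
    trial's mean around the subject-condition mean.
    """

    mean_mm2: Mapping[str, float] = field(
        default_factory=lambda: {"tRelaxed": 270.9, "tStressed": 284.6})
    within_trial_sd_mm2: Mapping[str, float] = field(
        default_factory=lambda: {"tRelaxed": 16.7, "tStressed": 21.2})
    between_subject_sd_mm2: float = 26.7
    task_type_sd_mm2: float = 15.0     # subject-specific task-type offsets (mean area)
    task_type_sd_of_sd_mm2: float = 3.0  # same, for the within-trial SD
    condition_noise_sd_mm2: float = 8.0
    sd_between_subject_sd_mm2: float = 6.8
    trial_level_sd_mm2: float = 8.0
    axis_ratio_log_mean: float = math.log(1.5)
    axis_ratio_log_sd: float = 0.08


@dataclass(frozen=True)
class EffectSpec:
    """Standardised condition effects.  When a d is given it overrides the
    corresponding stressed-condition level of the area model:
    stressed mean = relaxed mean + d * sqrt(between^2 + condition_noise^2)."""

    d_area_mean: float | None = None
    d_area_sd: float | None = None


@dataclass(frozen=True)
class EDAModel:
    sample_rate_hz: float = 4.0
    tonic_uS: Mapping[str, float] = field(
        default_factory=lambda: {"tRelaxed": 2.057, "tStressed": 4.223})
    # slow tonic wandering; the period is kept long so the baseline slope
    # stays well below the 0.01 uS/sample scale an SCR detector looks for
    drift_amp_uS: float = 0.15
    drift_period_s: float = 600.0
    scr_rate_hz: Mapping[str, float] = field(
        default_factory=lambda: {"tRelaxed": 0.099, "tStressed": 0.167})
    refractory_s: float = 3.0
    amp_median_uS: Mapping[str, float] = field(
        default_factory=lambda: {"tRelaxed": 0.15, "tStressed": 0.25})
    amp_log_sd: float = 0.5
    rise_s: float = 0.75
    decay_s: float = 3.0
    noise_sd_uS: float = 0.003  # keeps the 0.01 uS SCR threshold above 3 sigma


@dataclass(frozen=True)
class SelfReportModel:
    """End-of-phase population means on the 0-10 scale (the marker value at
    the end of each phase is drawn around these)."""

    stress: Mapping[str, float] = field(default_factory=lambda: {
        "baseline": 3.0, "Relaxation": 2.27, "tRelaxed": 3.78,
        "Stressor": 6.22, "tStressed": 4.50})
    tension: Mapping[str, float] = field(default_factory=lambda: {
        "baseline": 2.5, "Relaxation": 1.5, "tRelaxed": 3.5,
        "Stressor": 6.0, "tStressed": 5.0})
    concentration_mean: float = 6.5
    marker_sd: float = 1.2


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 18
    n_relax_stress_arm: int | None = None  # None: the 8/18 study proportion
    arm_assignment: Mapping[str, str] | None = None  # subject_id -> arm override
    sampling_mean_ms: float = 8.17
    sampling_sd_ms: float = 3.75
    gap_probability: float = 0.38
    position_noise_mm: float = 0.1
    true_msd: Mapping[str, MSDTruth] = field(default_factory=lambda: {
        "tRelaxed": MSDTruth(0.538, 8.0), "tStressed": MSDTruth(0.540, 8.2)})
    area_model: AreaModel = field(default_factory=AreaModel)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    eda_model: EDAModel = field(default_factory=EDAModel)
    sr_model: SelfReportModel = field(default_factory=SelfReportModel)
    px_to_mm: float = 0.1
    stroke_duration_s: float | None = None  # None: settle-time based
    inter_trial_gap_s: float = 1.5  # stroke + gap ~ 3.3 s/trial, ~6.5 min phases
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ValueError("gap_probability must be in [0, 1]")
        if self.sampling_mean_ms <= 0 or self.sampling_sd_ms < 0:
            raise ValueError("sampling interval moments must be positive")
        if self.stroke_duration_s is not None and self.stroke_duration_s <= 0:
            raise ValueError("stroke duration must be positive")
        if self.position_noise_mm < 0:
            raise ValueError("position noise must be non-negative")
        for cond in CONDITIONS:
            if cond not in self.true_msd:
                raise ValueError(f"true_msd missing condition {cond}")
        em = self.eda_model
        for cond in CONDITIONS:
            if em.scr_rate_hz[cond] > 0 and em.scr_rate_hz[cond] >= 1.0 / em.refractory_s:
                raise ValueError("scr rate must stay below 1/refractory")

    # --- derived condition-level area parameters (effect overrides applied) ---
    def area_condition_mean(self, condition: str) -> float:
        am, es = self.area_model, self.effect_spec
        if es.d_area_mean is None or condition == "tRelaxed":
            return float(am.mean_mm2[condition])
        sigma = math.hypot(am.between_subject_sd_mm2, am.condition_noise_sd_mm2)
        return float(am.mean_mm2["tRelaxed"] + es.d_area_mean * sigma)

    def area_condition_within_sd(self, condition: str) -> float:
        am, es = self.area_model, self.effect_spec
        if es.d_area_sd is None or condition == "tRelaxed":
            return float(am.within_trial_sd_mm2[condition])
        sigma = math.hypot(am.sd_between_subject_sd_mm2, am.condition_noise_sd_mm2 / 4)
        return float(am.within_trial_sd_mm2["tRelaxed"] + es.d_area_sd * sigma)


def noise_free_config(**overrides) -> GeneratorConfig:
    """Idealised conditions for exact-recovery checks: no positional noise,
    no sampling jitter (uniform 10 ms grid), no gap artifacts."""
    defaults = dict(sampling_mean_ms=10.0, sampling_sd_ms=0.0,
                    gap_probability=0.0, position_noise_mm=0.0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def _rng(config: GeneratorConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *[k & 0xFFFFFFFF for k in keys]])


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

def generate_task_schedule(subject_id: str, condition: str,
                           config: GeneratorConfig) -> list[TrialSpec]:
    """One condition block: 120 trials (3 task-type blocks x 20 configs x 2 reps).

    Task-type block order is randomised per subject (identical across the
    subject's two conditions); within a block the 40 trials are shuffled per
    subject-and-condition.  Fully determined by the config seed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition}")
    block_rng = _rng(config, _key(subject_id), _STREAM_BLOCK)
    task_order = list(TASK_TYPES)
    block_rng.shuffle(task_order)
    cfg_rng = _rng(config, _key(subject_id), _key(condition), _STREAM_CONFIG)
    trials: list[TrialSpec] = []
    for task_type in task_order:
        block = [(d, w, rep)
                 for d in TASK_DISTANCES_PX
                 for w in TASK_WIDTHS_PX[task_type]
                 for rep in (1, 2)]
        cfg_rng.shuffle(block)
        for d, w, rep in block:
            i = len(trials)
            trials.append(TrialSpec(
                trial_id=f"{subject_id}:{condition}:{i:03d}",
                subject_id=subject_id,
                condition=condition,
                task_config=TaskConfig(task_type, d, w),
                repetition=rep,
                order_index=i,
            ))
    return trials


# ---------------------------------------------------------------------------
# touch-log synthesis
# ---------------------------------------------------------------------------

def _subject_area_params(subject_id: str, condition: str, task_type: str,
                         config: GeneratorConfig):
    """Subject-by-condition contact-area mean and within-trial SD (mm^2).

    The subject offset and the subject's task-type offsets are shared across
    conditions (they cancel in paired comparisons but spread the per-subject
    normalization range); the condition deviation gives paired differences a
    nonzero variance.
    """
    am = config.area_model
    base_rng = _rng(config, _key(subject_id), _STREAM_AREA)
    subj_offset = base_rng.normal(0.0, am.between_subject_sd_mm2)
    subj_sd_offset = base_rng.normal(0.0, am.sd_between_subject_sd_mm2)
    task_rng = _rng(config, _key(subject_id), _key(task_type), _STREAM_AREA)
    task_offset = task_rng.normal(0.0, am.task_type_sd_mm2)
    task_sd_offset = task_rng.normal(0.0, am.task_type_sd_of_sd_mm2)
    cond_rng = _rng(config, _key(subject_id), _key(condition), _STREAM_AREA)
    mean = (config.area_condition_mean(condition) + subj_offset + task_offset
            + cond_rng.normal(0.0, am.condition_noise_sd_mm2))
    sd = (config.area_condition_within_sd(condition) + subj_sd_offset + task_sd_offset
          + cond_rng.normal(0.0, am.condition_noise_sd_mm2 / 4))
    return max(mean, 30.0), max(sd, 1.0)


def _truncnorm_loc(mean: float, sd: float, lo: float) -> float:
    """Location parameter such that the lower-truncated normal keeps the
    requested mean (fixed-point on the Mills-ratio shift)."""
    loc = mean
    for _ in range(6):
        a = (lo - loc) / sd
        shift = sd * sps.norm.pdf(a) / sps.norm.sf(a)
        loc = mean - shift
    return loc


def _sample_intervals(n: int, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    mean_s = config.sampling_mean_ms / 1000.0
    sd_s = config.sampling_sd_ms / 1000.0
    if sd_s == 0.0:
        return np.full(n, mean_s)
    lo = 0.0005  # intervals are strictly positive (>=0.5 ms)
    loc = _truncnorm_loc(mean_s, sd_s, lo)
    a = (lo - loc) / sd_s
    return sps.truncnorm.rvs(a, np.inf, loc=loc, scale=sd_s, size=n, random_state=rng)


def _sample_areas(n: int, mean: float, sd: float, rng: np.random.Generator):
    """Per-sample areas as lognormals with the requested mean/SD, split into
    correlated major/minor axes (so pi*a*b reproduces the area exactly and
    a >= b always)."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2.0
    area = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    ratio = np.maximum(np.exp(rng.normal(math.log(1.5), 0.08, size=n)), 1.02)
    major = np.sqrt(area * ratio / math.pi)
    minor = np.sqrt(area / (ratio * math.pi))
    return area, major, minor


def stroke_duration(truth: MSDTruth, config: GeneratorConfig) -> float:
    if config.stroke_duration_s is not None:
        return config.stroke_duration_s
    return max(1.2, 9.0 / (truth.zeta * truth.omega_n))


def simulate_stroke(trial: TrialSpec, config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthesize one trial's touch events (a single continuous stroke).

    x(t) follows the underdamped step response toward the target distance
    (pixels scaled to mm), sampled at jittered intervals, with additive
    positional noise; y stays near the pad's horizontal midline; ellipse
    axes realise the configured contact-area distribution.
    """
    truth = config.true_msd[trial.condition]
    if rng is None:
        rng = _rng(config, _key(trial.trial_id), _STREAM_STROKE)
    duration = stroke_duration(truth, config)
    if duration <= 0:
        raise ValueError("non-positive stroke duration")
    # accumulate jittered timestamps until the duration is covered
    n_guess = int(duration / (config.sampling_mean_ms / 1000.0)) + 8
    t = np.concatenate(([0.0], np.cumsum(_sample_intervals(n_guess, config, rng))))
    t = t[t <= duration]
    d_mm = trial.task_config.distance_px * config.px_to_mm
    x0 = 5.0
    # an underdamped stroke overshoots by exp(-zeta*pi/sqrt(1-zeta^2)); keep
    # the whole trajectory on the 140 mm pad (Gamma/omega are amplitude-
    # invariant, so scaling the step never changes the recovered dynamics)
    overshoot = 1.0 + math.exp(-truth.zeta * math.pi / math.sqrt(1.0 - truth.zeta**2))
    margin = 2.0 + 5.0 * config.position_noise_mm
    d_mm = min(d_mm, (140.0 - x0 - margin) / overshoot)
    x = x0 + step_response(t, d_mm, truth.zeta, truth.omega_d_rad_s)
    if config.position_noise_mm > 0:
        x = x + rng.normal(0.0, config.position_noise_mm, size=t.size)
    x = np.clip(x, 0.0, 140.0)
    y = np.clip(35.0 + rng.normal(0.0, 0.05, size=t.size), 0.0, 70.0)
    mean_area, sd_area = _subject_area_params(
        trial.subject_id, trial.condition, trial.task_config.task_type, config)
    trial_mean = max(mean_area + rng.normal(0.0, config.area_model.trial_level_sd_mm2), 30.0)
    _, major, minor = _sample_areas(t.size, trial_mean, sd_area, rng)
    state = "touching" if trial.task_config.task_type == "click" else "dragging"
    return pd.DataFrame({
        "t_s": t,
        "finger_id": np.zeros(t.size, dtype=int),
        "x_mm": x,
        "y_mm": y,
        "major_mm": major,
        "minor_mm": minor,
        "state": state,
        "pressed": True,
    }, columns=EVENT_COLUMNS)


def inject_artifacts(events: pd.DataFrame, config: GeneratorConfig,
                     trial_rng: np.random.Generator) -> pd.DataFrame:
    """Emulate multi-finger discontinuities.

    With probability ``gap_probability`` the trial receives a gap: a
    contiguous 50-300 ms span inside the middle 80% of the trial is removed
    and the samples after it are relabelled with a new finger id (lift and
    re-placement).  With probability 0.3, given a gap, a short concurrent
    low-displacement secondary trace from another finger is added.  The
    largest remaining segment still carries most of the step displacement.
    """
    if events.empty:
        raise ValueError("inject_artifacts requires a nonempty trial")
    if trial_rng.random() >= config.gap_probability:
        return events
    t = events["t_s"].to_numpy()
    t0, t1 = t[0], t[-1]
    span = t1 - t0
    gap_len = trial_rng.uniform(0.05, min(0.3, 0.4 * span))
    lo = t0 + 0.1 * span
    hi = t1 - 0.1 * span - gap_len
    onset = trial_rng.uniform(lo, max(lo, hi))
    keep = (t < onset) | (t >= onset + gap_len)
    out = events[keep].copy().reset_index(drop=True)
    after = out["t_s"].to_numpy() >= onset
    out.loc[after, "finger_id"] = out["finger_id"].max() + 1
    if trial_rng.random() < 0.3 and span > 0.5:
        # concurrent secondary finger: brief, nearly stationary trace
        n2 = int(trial_rng.integers(8, 20))
        start = trial_rng.uniform(t0 + 0.1 * span, t1 - 0.3 * span)
        ts = start + np.cumsum(_sample_intervals(n2, config, trial_rng))
        xs = trial_rng.uniform(5.0, 130.0) + trial_rng.normal(0.0, 0.2, n2)
        med_major = float(events["major_mm"].median())
        med_minor = float(events["minor_mm"].median())
        sec = pd.DataFrame({
            "t_s": ts,
            "finger_id": int(out["finger_id"].max()) + 1,
            "x_mm": np.clip(xs, 0, 140),
            "y_mm": np.clip(30.0 + trial_rng.normal(0.0, 0.1, n2), 0, 70),
            "major_mm": med_major * np.exp(trial_rng.normal(0, 0.05, n2)),
            "minor_mm": med_minor * np.exp(trial_rng.normal(0, 0.05, n2)),
            "state": "touching",
            "pressed": True,
        }, columns=EVENT_COLUMNS)
        out = pd.concat([out, sec], ignore_index=True).sort_values(
            "t_s", kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# EDA synthesis
# ---------------------------------------------------------------------------

def _scr_pulse(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak biexponential pulse (zero before onset)."""
    shape = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s)
                     - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    tp = rise_s * decay_s / (decay_s - rise_s) * math.log(decay_s / rise_s)
    peak = math.exp(-tp / decay_s) - math.exp(-tp / rise_s)
    return shape / peak


def simulate_eda(phase_duration_s: float, condition: str, config: GeneratorConfig,
                 rng: np.random.Generator | None = None):
    """Synthesize one phase's EDA: tonic drift + SCR pulses + noise at 4 Hz.

    Returns ``(EDASeries, truth)`` where truth holds the tonic level and the
    injected pulse onset times / peak amplitudes (uS).
    """
    if phase_duration_s <= 0:
        raise ValueError("phase duration must be positive")
    em = config.eda_model
    if rng is None:
        rng = _rng(config, _key(condition), _STREAM_EDA)
    fs = em.sample_rate_hz
    n = int(round(phase_duration_s * fs))
    t = np.arange(n) / fs
    phase0 = rng.uniform(0, 2 * math.pi)
    tonic = em.tonic_uS[condition] + em.drift_amp_uS * np.sin(
        2 * math.pi * t / em.drift_period_s + phase0)
    y = tonic.copy()
    rate = em.scr_rate_hz[condition]
    times: list[float] = []
    amps: list[float] = []
    if rate > 0:
        lam = 1.0 / (1.0 / rate - em.refractory_s)
        cursor = float(rng.exponential(1.0 / lam))
        while cursor < phase_duration_s - 1.0:
            amp = float(rng.lognormal(math.log(em.amp_median_uS[condition]), em.amp_log_sd))
            y += amp * _scr_pulse(t - cursor, em.rise_s, em.decay_s)
            times.append(cursor)
            amps.append(amp)
            cursor += em.refractory_s + float(rng.exponential(1.0 / lam))
    if em.noise_sd_uS > 0:
        y = y + rng.normal(0.0, em.noise_sd_uS, size=n)
    y = np.maximum(y, 0.0)
    truth = {
        "tonic_level_uS": float(em.tonic_uS[condition]),
        "scr_times_s": times,
        "scr_amplitudes_uS": amps,
    }
    return EDASeries(t, y, fs), truth


# ---------------------------------------------------------------------------
# self-reports
# ---------------------------------------------------------------------------

def _marker_means(arm: str, scale_means: Mapping[str, float]) -> dict[str, float]:
    """End-of-phase means laid onto the arm's marker sequence."""
    if arm == "Relax-Stress":
        seq = ["baseline", "Relaxation", "tRelaxed", "baseline", "Stressor", "tStressed"]
    else:
        seq = ["baseline", "Stressor", "tStressed", "baseline", "Relaxation", "tRelaxed"]
    return {m: scale_means[p] for m, p in zip(SR_MARKERS, seq)}


def simulate_self_reports(subject_id: str, arm: str, config: GeneratorConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Six marker records (stress / tension / concentration, integer 0-10)."""
    srm = config.sr_model
    if rng is None:
        rng = _rng(config, _key(subject_id), _STREAM_SR)
    stress_mu = _marker_means(arm, srm.stress)
    tension_mu = _marker_means(arm, srm.tension)
    rows = []
    for m in SR_MARKERS:
        def draw(mu: float) -> int:
            return int(np.clip(round(rng.normal(mu, srm.marker_sd)), 0, 10))
        rows.append({
            "subject_id": subject_id, "marker": m,
            "stress": draw(stress_mu[m]),
            "tension": draw(tension_mu[m]),
            "concentration": draw(srm.concentration_mean),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-study assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionData:
    condition: str
    schedule: tuple[TrialSpec, ...]
    events: pd.DataFrame = field(repr=False)
    annotations: pd.DataFrame = field(repr=False)
    eda: EDASeries = field(repr=False)
    eda_truth: dict = field(repr=False)
    phase_duration_s: float = 0.0


@dataclass(frozen=True)
class SubjectData:
    subject_id: str
    arm: str
    self_reports: pd.DataFrame = field(repr=False)
    conditions: Mapping[str, ConditionData] = field(repr=False)


@dataclass(frozen=True)
class StudyDataset:
    config: GeneratorConfig
    subjects: tuple[SubjectData, ...]

    @property
    def arm_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.subjects:
            out[s.arm] = out.get(s.arm, 0) + 1
        return out

    def ground_truth(self) -> dict:
        cfg = self.config
        return {
            "seed": cfg.seed,
            "true_msd": {c: asdict(cfg.true_msd[c]) for c in CONDITIONS},
            "area_mean_mm2": {c: cfg.area_condition_mean(c) for c in CONDITIONS},
            "area_within_sd_mm2": {c: cfg.area_condition_within_sd(c) for c in CONDITIONS},
            "gap_probability": cfg.gap_probability,
            "eda": {c: {"tonic_uS": cfg.eda_model.tonic_uS[c],
                        "scr_rate_hz": cfg.eda_model.scr_rate_hz[c]}
                    for c in CONDITIONS},
        }


def subject_ids(config: GeneratorConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_subjects)]


def arm_of(subject_id: str, config: GeneratorConfig) -> str:
    if config.arm_assignment and subject_id in config.arm_assignment:
        return config.arm_assignment[subject_id]
    n_first = config.n_relax_stress_arm
    if n_first is None:
        # the study's 8/18 proportion, at least 2 per arm where possible
        n_first = max(2, round(config.n_subjects * 8 / 18))
        n_first = min(n_first, config.n_subjects - 2)
    idx = int(subject_id[1:]) - 1
    return ARMS[0] if idx < n_first else ARMS[1]


def _simulate_condition(subject_id: str, condition: str,
                        config: GeneratorConfig) -> ConditionData:
    schedule = generate_task_schedule(subject_id, condition, config)
    frames: list[pd.DataFrame] = []
    annotations: list[TrialAnnotation] = []
    cursor = 0.0
    for trial in schedule:
        srng = _rng(config, _key(trial.trial_id), _STREAM_STROKE)
        ev = simulate_stroke(trial, config, srng)
        arng = _rng(config, _key(trial.trial_id), _STREAM_ARTIFACT)
        ev = inject_artifacts(ev, config, arng)
        t_end = float(ev["t_s"].iloc[-1])
        ev = ev.assign(t_s=ev["t_s"] + cursor)
        frames.append(ev)
        annotations.append(TrialAnnotation(
            trial_id=trial.trial_id, subject_id=subject_id,
            phase=condition, condition=condition,
            task_type=trial.task_config.task_type,
            distance_px=trial.task_config.distance_px,
            width_px=trial.task_config.width_px,
            t_start_s=cursor, t_end_s=cursor + t_end + 1e-6,
        ))
        cursor += t_end + config.inter_trial_gap_s
    events = pd.concat(frames, ignore_index=True)
    ann = pd.DataFrame([a.__dict__ for a in annotations])
    erng = _rng(config, _key(subject_id), _key(condition), _STREAM_EDA)
    eda, eda_truth = simulate_eda(cursor, condition, config, erng)
    return ConditionData(condition, tuple(schedule), events, ann, eda, eda_truth, cursor)


def simulate_study(config: GeneratorConfig = GeneratorConfig()) -> StudyDataset:
    """Generate a complete counterbalanced study.

    Per subject: arm assignment, six self-report markers, and for each of
    the two task phases a 120-trial schedule with touch logs, annotations
    and a phase-long EDA series.  Byte-identical for identical configs.
    """
    config.validate()
    if config.n_subjects < 2:
        raise ValueError("paired analysis needs at least 2 subjects")
    subjects = []
    for sid in subject_ids(config):
        arm = arm_of(sid, config)
        reports = simulate_self_reports(sid, arm, config)
        conds = {c: _simulate_condition(sid, c, config) for c in CONDITIONS}
        subjects.append(SubjectData(sid, arm, reports, conds))
    return StudyDataset(config, tuple(subjects))
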