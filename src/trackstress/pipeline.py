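"""End-to-end orchestration: simulate -> segment -> metrics/MSD -> EDA -> analyze.

The statistical protocol mirrors the study design:

1. *Mixed-Task model*: per subject and condition, each finger-dynamics
   measure is averaged over each task type's 40 trials, min-max normalized
   per subject across the six task-type-by-condition cells, then averaged
   (unweighted) over the three task types; the mass-spring-damper
   parameters Gamma and omega stay on their native scales.  Each measure
   gets a routed one-tailed paired comparison.
2. *Task-Specific models*: per-task-type comparisons of contact-area mean
   and SD, Bonferroni-corrected at 0.05/3.
3. *Sensitivity*: click trials only — the initial 10% (4 of 40 trials,
   closest to the stressor) and a "decimated" subset (first, last and two
   random trials) on raw mm^2 values.
4. *Order checks*: Order x Condition interaction ANOVAs for the contact-area
   measures.
5. *Validation*: self-report (min-max across the four phases, during-phase
   values from bracketing markers) and EDA (tonic mean, phasic mean, SCR
   count per task phase) comparisons confirm the stressor worked.

All stages are deterministic under a fixed seed; intermediates are plain
CSV/JSON so any stage can be rerun or replaced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eda_processing import EDASeries, eda_phase_summary, screen_quality
from .event_log import assign_events_to_trials, read_event_log, write_event_log
from .finger_dynamics import (
    METRIC_FIELDS, MIXED_TASK, PER_TASK_TYPE, aggregate_phase, metrics_table,
    trial_metrics,
)
from .msd_model import estimate_trial_msd
from .stats_analysis import (
    bonferroni_alpha, correlate, during_phase_value, minmax_normalize,
    order_condition_anova, paired_compare, subset_decimated, subset_initial,
)
from .stroke_segmentation import SegmentationConfig, gap_statistics, split_strokes
from .synthetic_data import (
    CONDITIONS, SR_PHASE_MARKERS, GeneratorConfig, StudyDataset, simulate_study,
)

logger = logging.getLogger("trackstress")

MIXED_MEASURES = list(METRIC_FIELDS)  # normalized; gamma/omega handled raw
AREA_MEASURES = ("mean_area_mm2", "sd_area_mm2")


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    grid_ms: float = 10.0
    axes_are_full: bool = False
    alpha: float = 0.05
    bonferroni_m: int = 3
    decimation_seed: int = 1234

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        from .synthetic_data import AreaModel, EDAModel, EffectSpec, MSDTruth, SelfReportModel
        gen = dict(raw.get("generator", {}))
        if "true_msd" in gen:
            gen["true_msd"] = {k: MSDTruth(**v) for k, v in gen["true_msd"].items()}
        for key, klass in (("area_model", AreaModel), ("effect_spec", EffectSpec),
                           ("eda_model", EDAModel), ("sr_model", SelfReportModel)):
            if key in gen:
                gen[key] = klass(**gen[key])
        seg = SegmentationConfig(**raw.get("segmentation", {}))
        extra = {k: v for k, v in raw.items() if k not in ("generator", "segmentation")}
        return cls(generator=GeneratorConfig(**gen), segmentation=seg, **extra)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# per-subject feature extraction
# ---------------------------------------------------------------------------

def extract_trial_table(events: pd.DataFrame, annotations: pd.DataFrame,
                        config: PipelineConfig) -> tuple[pd.DataFrame, float]:
    """Segment every trial and compute metrics + MSD parameters.

    Returns the per-trial table (metrics columns, gamma, omega_rad_s,
    task_type, order from the annotation row order) and the subject's
    gap fraction.
    """
    assignment = assign_events_to_trials(events, annotations)
    seg_results = {}
    metrics = {}
    msd_rows = {}
    for trial_id, ev in assignment.by_trial.items():
        seg = split_strokes(ev, config.segmentation)
        seg_results[trial_id] = seg
        metrics[trial_id] = trial_metrics(seg.strokes, config.axes_are_full)
        p = estimate_trial_msd(ev, config.segmentation, config.grid_ms)
        if p is not None and p.usable:
            msd_rows[trial_id] = (p.damping_ratio_gamma, p.damped_frequency_omega)
        else:
            msd_rows[trial_id] = (np.nan, np.nan)
    table = metrics_table(metrics, annotations)
    table["gamma"] = table["trial_id"].map(lambda t: msd_rows.get(t, (np.nan, np.nan))[0])
    table["omega_rad_s"] = table["trial_id"].map(lambda t: msd_rows.get(t, (np.nan, np.nan))[1])
    table = table.sort_values("t_start_s", kind="stable").reset_index(drop=True)
    table["production_order"] = np.arange(len(table))
    gap_fraction = gap_statistics(seg_results) if seg_results else float("nan")
    return table, gap_fraction


def _per_task_values(table: pd.DataFrame, measure: str) -> pd.Series:
    """Mean of a per-trial measure over each task type's valid trials."""
    valid = table[np.isfinite(table[measure])]
    if measure in METRIC_FIELDS:
        valid = valid[valid["n_strokes_used"] > 0]
    out = valid.groupby("task_type")[measure].mean()
    return out


def subject_condition_features(table: pd.DataFrame) -> dict:
    """Per-task-type and msd condition-level values for one subject/condition."""
    feats: dict = {"per_task": {}, "msd": {}}
    for m in MIXED_MEASURES:
        feats["per_task"][m] = _per_task_values(table, m)
    for m in ("gamma", "omega_rad_s"):
        vals = _per_task_values(table, m)
        feats["msd"][m] = float(vals.mean()) if len(vals) == 3 else float("nan")
    click = table[table["task_type"] == "click"].sort_values("production_order")
    click = click[click["n_strokes_used"] > 0]
    feats["click_trials"] = click
    return feats


# ---------------------------------------------------------------------------
# study-level analysis
# ---------------------------------------------------------------------------

def _result_dict(res) -> dict:
    return res.as_dict()


def analyze_self_reports(study: StudyDataset) -> dict:
    """Min-max normalized during-phase self-report comparisons."""
    per_phase: dict[str, dict[str, list[float]]] = {
        scale: {p: [] for p in ("Relaxation", "tRelaxed", "Stressor", "tStressed")}
        for scale in ("stress", "tension", "concentration")}
    flat_stress, flat_tension = [], []
    for subj in study.subjects:
        sr = subj.self_reports.set_index("marker")
        markers = SR_PHASE_MARKERS[subj.arm]
        for scale in per_phase:
            raw = {phase: during_phase_value(float(sr.loc[b, scale]), float(sr.loc[a, scale]))
                   for phase, (b, a) in markers.items()}
            try:
                norm = minmax_normalize([raw[p] for p in per_phase[scale]])
            except ValueError:
                continue  # degenerate subject flagged out of this scale
            for p, v in zip(per_phase[scale], norm):
                per_phase[scale][p].append(float(v))
            if scale == "stress":
                flat_stress.extend(norm)
            elif scale == "tension":
                flat_tension.extend(norm)
    out: dict = {}
    for scale, phases in per_phase.items():
        out[scale] = {
            "stressor_vs_relaxation": _result_dict(paired_compare(
                phases["Relaxation"], phases["Stressor"], "greater")),
            "tstressed_vs_trelaxed": _result_dict(paired_compare(
                phases["tRelaxed"], phases["tStressed"], "greater")),
            "phase_means": {p: float(np.mean(v)) for p, v in phases.items()},
        }
    n = min(len(flat_stress), len(flat_tension))
    corr = correlate(flat_stress[:n], flat_tension[:n])
    out["tension_stress_correlation"] = {
        "method": corr.method, "coefficient": corr.coefficient, "p_value": corr.p_value}
    return out


def analyze_eda(study: StudyDataset) -> dict:
    """Per-subject task-phase EDA summaries and paired comparisons.

    Subjects whose recording fails the quality screen are excluded (counted).
    The two phase series are concatenated in the subject's arm order so SCR
    detection runs once per subject.
    """
    rows = []
    excluded = 0
    for subj in study.subjects:
        order = ("tRelaxed", "tStressed") if subj.arm == "Relax-Stress" else ("tStressed", "tRelaxed")
        first = subj.conditions[order[0]]
        second = subj.conditions[order[1]]
        offset = first.eda.t_s[-1] + 1.0 / first.eda.sample_rate_hz
        combined = EDASeries(
            np.concatenate([first.eda.t_s, second.eda.t_s + offset]),
            np.concatenate([first.eda.eda_uS, second.eda.eda_uS]),
            first.eda.sample_rate_hz)
        if screen_quality(combined).excluded:
            excluded += 1
            continue
        windows = {order[0]: (0.0, offset),
                   order[1]: (offset, offset + second.eda.t_s[-1] + 1.0)}
        summary = eda_phase_summary(combined, windows)
        for row in summary.itertuples(index=False):
            rows.append({"subject_id": subj.subject_id, **row._asdict()})
    df = pd.DataFrame(rows)
    out: dict = {"n_excluded": excluded, "n_analyzed": df["subject_id"].nunique() if len(df) else 0}
    for measure in ("tonic_mean_uS", "phasic_mean_uS", "scr_count"):
        wide = df.pivot(index="subject_id", columns="phase", values=measure)
        out[measure] = _result_dict(paired_compare(
            wide["tRelaxed"].to_numpy(float), wide["tStressed"].to_numpy(float), "greater"))
        out[measure + "_means"] = {c: float(wide[c].mean()) for c in CONDITIONS}
    return out


def analyze_finger_dynamics(features_by_subject: dict, study: StudyDataset,
                            config: PipelineConfig) -> dict:
    """Mixed-Task, Task-Specific, sensitivity and order-interaction analyses."""
    subjects = list(features_by_subject)
    arms = {s.subject_id: s.arm for s in study.subjects}
    task_types = ("click", "drag_and_drop", "steer")

    # per-subject normalized cell values: measure -> condition -> task -> value
    norm_cells: dict[str, dict] = {m: {} for m in MIXED_MEASURES}
    for sid in subjects:
        for m in MIXED_MEASURES:
            cells = []
            for cond in CONDITIONS:
                pt = features_by_subject[sid][cond]["per_task"][m]
                cells.extend(float(pt[t]) for t in task_types)
            norm = minmax_normalize(cells)
            norm_cells[m][sid] = {
                cond: dict(zip(task_types, norm[i * 3:(i + 1) * 3]))
                for i, cond in enumerate(CONDITIONS)}

    report: dict = {"mixed_task": {}, "task_specific": {}, "sensitivity": {},
                    "order_condition_anova": {}}

    def paired_vectors(values_fn):
        x = [values_fn(sid, "tRelaxed") for sid in subjects]
        y = [values_fn(sid, "tStressed") for sid in subjects]
        return np.asarray(x, float), np.asarray(y, float)

    # --- Mixed-Task model ---------------------------------------------------
    mixed_values: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for m in MIXED_MEASURES:
        x, y = paired_vectors(lambda sid, c: float(np.mean(list(norm_cells[m][sid][c].values()))))
        mixed_values[m] = (x, y)
        report["mixed_task"]["normalized_" + m] = _result_dict(paired_compare(x, y, "greater"))
    for m in ("gamma", "omega_rad_s"):
        x, y = paired_vectors(lambda sid, c: features_by_subject[sid][c]["msd"][m])
        mixed_values[m] = (x, y)
        report["mixed_task"][m] = _result_dict(paired_compare(x, y, "greater"))

    # --- Task-Specific models (contact area, Bonferroni 0.05/3) -------------
    alpha_ts = bonferroni_alpha(config.alpha, config.bonferroni_m)
    report["task_specific"]["bonferroni_alpha"] = alpha_ts
    for m in AREA_MEASURES:
        per_task = {}
        for task in task_types:
            x, y = paired_vectors(lambda sid, c: norm_cells[m][sid][c][task])
            per_task[task] = _result_dict(paired_compare(x, y, "greater"))
        report["task_specific"]["normalized_" + m] = per_task

    # --- Sensitivity on raw click areas --------------------------------------
    def click_subset_vectors(m, subset_fn):
        def value(sid, cond):
            trials = features_by_subject[sid][cond]["click_trials"]
            vals = list(trials[m])
            return float(np.mean(subset_fn(vals)))
        return paired_vectors(value)

    rng = np.random.default_rng(config.decimation_seed)
    sens: dict = {}
    for m in AREA_MEASURES:
        x, y = click_subset_vectors(m, lambda v: subset_initial(v, 0.10))
        sens.setdefault("initial_10pct", {})[m] = _result_dict(paired_compare(x, y, "greater")) | {
            "means": {"tRelaxed": float(np.mean(x)), "tStressed": float(np.mean(y))}}
        x, y = click_subset_vectors(m, lambda v: subset_decimated(v, rng))
        sens.setdefault("decimated", {})[m] = _result_dict(paired_compare(x, y, "greater")) | {
            "means": {"tRelaxed": float(np.mean(x)), "tStressed": float(np.mean(y))}}
    report["sensitivity"] = sens

    # --- Order x Condition interactions --------------------------------------
    for m in AREA_MEASURES:
        x, y = mixed_values[m]  # normalized mixed-task values
        long = pd.DataFrame({
            "subject_id": subjects * 2,
            "order_arm": [arms[s] for s in subjects] * 2,
            "condition": ["tRelaxed"] * len(subjects) + ["tStressed"] * len(subjects),
            "value": np.concatenate([x, y]),
        })
        report["order_condition_anova"]["mixed_normalized_" + m] = _result_dict(
            order_condition_anova(long))
    return report


def extract_features(study: StudyDataset, config: PipelineConfig):
    """Per-subject feature extraction for every condition.

    Returns ``(features, gap_fractions)``; each feature entry keeps the full
    per-trial table under ``"table"``.
    """
    features: dict = {}
    gap_fractions = []
    for subj in study.subjects:
        features[subj.subject_id] = {}
        for cond in CONDITIONS:
            cd = subj.conditions[cond]
            table, gap_frac = extract_trial_table(cd.events, cd.annotations, config)
            features[subj.subject_id][cond] = subject_condition_features(table)
            features[subj.subject_id][cond]["table"] = table
            gap_fractions.append(gap_frac)
    return features, gap_fractions


def analyze_study(study: StudyDataset, config: PipelineConfig | None = None,
                  features: dict | None = None, gap_fractions=None) -> dict:
    """Run the full statistical protocol on a (simulated or loaded) study."""
    config = config or PipelineConfig(generator=study.config)
    if features is None:
        features, gap_fractions = extract_features(study, config)
    report = {
        "n_subjects": len(study.subjects),
        "arm_counts": study.arm_counts,
        "gap_fraction_mean": float(np.nanmean(gap_fractions)),
        "self_report": analyze_self_reports(study),
        "eda": analyze_eda(study),
    }
    report.update(analyze_finger_dynamics(features, study, config))
    return report


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def write_study(study: StudyDataset, out_dir) -> None:
    out = Path(out_dir)
    (out / "logs").mkdir(parents=True, exist_ok=True)
    (out / "eda").mkdir(exist_ok=True)
    reports = []
    for subj in study.subjects:
        reports.append(subj.self_reports.assign(arm=subj.arm))
        for cond in CONDITIONS:
            cd = subj.conditions[cond]
            stem = f"{subj.subject_id}_{cond}"
            write_event_log(cd.events, cd.annotations,
                            out / "logs" / f"{stem}_events.csv",
                            out / "logs" / f"{stem}_annotations.csv")
            pd.DataFrame({"t_s": cd.eda.t_s, "eda_uS": cd.eda.eda_uS}).to_csv(
                out / "eda" / f"{stem}.csv", index=False)
    pd.concat(reports, ignore_index=True).to_csv(out / "self_reports.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(study.ground_truth(), fh, indent=2)


def load_subject_tables(out_dir, config: PipelineConfig) -> pd.DataFrame:
    """Re-run segmentation + metrics + MSD from the CSV intermediates."""
    out = Path(out_dir)
    tables = []
    for ev_path in sorted((out / "logs").glob("*_events.csv")):
        ann_path = ev_path.with_name(ev_path.name.replace("_events", "_annotations"))
        events, annotations = read_event_log(ev_path, ann_path)
        table, gap = extract_trial_table(events, annotations, config)
        table["subject_id"] = annotations["subject_id"].iloc[0]
        table["gap_fraction"] = gap
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """simulate -> write intermediates -> metrics/MSD -> analyze -> report files.

    Writes ``analysis_report.json``, ``trial_metrics.csv`` and
    ``manifest.json`` under ``out_dir`` and returns the report dict.
    Rerunning with the same config reproduces the outputs exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating study (n=%d, seed=%d)",
                config.generator.n_subjects, config.generator.seed)
    study = simulate_study(config.generator)
    write_study(study, out)
    logger.info("extracting metrics and running the statistical protocol")
    features, gap_fractions = extract_features(study, config)
    report = analyze_study(study, config, features, gap_fractions)
    tables = [features[sid][cond]["table"].assign(subject_id=sid)
              for sid in features for cond in CONDITIONS]
    pd.concat(tables, ignore_index=True).to_csv(out / "trial_metrics.csv", index=False)
    with open(out / "analysis_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    manifest = {"config_hash": _config_hash(config), "seed": config.generator.seed,
                "version": __version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
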