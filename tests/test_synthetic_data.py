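"""Generator: schedules, strokes, artifacts, EDA, self-reports, whole studies."""

import numpy as np
import pandas as pd
import pytest

from trackstress.msd_model import step_response
from trackstress.synthetic_data import (
    CONDITIONS, GeneratorConfig, MSDTruth, SR_MARKERS, arm_of,
    generate_task_schedule, inject_artifacts, noise_free_config, simulate_eda,
    simulate_self_reports, simulate_stroke, simulate_study, subject_ids,
)


class TestSchedule:
    def test_counts(self, default_config):
        sched = generate_task_schedule("S01", "tRelaxed", default_config)
        assert len(sched) == 120
        per_task = pd.Series([s.task_config.task_type for s in sched]).value_counts()
        assert set(per_task) == {40}
        for task in per_task.index:
            cfgs = {(s.task_config.distance_px, s.task_config.width_px)
                    for s in sched if s.task_config.task_type == task}
            assert len(cfgs) == 20

    def test_blocks_contiguous(self, default_config):
        sched = generate_task_schedule("S03", "tStressed", default_config)
        tasks = [s.task_config.task_type for s in sched]
        # grouped: the task type changes exactly twice along the sequence
        changes = sum(a != b for a, b in zip(tasks, tasks[1:]))
        assert changes == 2

    def test_same_seed_identical(self, default_config):
        a = generate_task_schedule("S02", "tRelaxed", default_config)
        b = generate_task_schedule("S02", "tRelaxed", default_config)
        assert a == b

    def test_block_order_shared_across_conditions(self, default_config):
        r = generate_task_schedule("S02", "tRelaxed", default_config)
        s = generate_task_schedule("S02", "tStressed", default_config)
        order = lambda sch: list(dict.fromkeys(t.task_config.task_type for t in sch))
        assert order(r) == order(s)


class TestStroke:
    def test_settles_to_target(self, clean_config, clean_trial):
        ev = simulate_stroke(clean_trial, clean_config)
        truth = clean_config.true_msd["tRelaxed"]
        d = clean_trial.task_config.distance_px * clean_config.px_to_mm
        x = ev["x_mm"].to_numpy() - ev["x_mm"].iloc[0]
        t = ev["t_s"].to_numpy()
        settle = 5.0 / (truth.zeta * truth.omega_n)
        assert abs(x[t > settle][-1] - d) < 0.01 * d

    def test_starts_at_rest(self, clean_config, clean_trial):
        ev = simulate_stroke(clean_trial, clean_config)
        assert ev["t_s"].iloc[0] == 0.0
        assert step_response(0.0, 100.0, 0.5, 8.0) == 0.0

    def test_underdamped_overshoot(self):
        cfg = noise_free_config(seed=1, true_msd={
            c: MSDTruth(0.3, 8.0) for c in CONDITIONS}, stroke_duration_s=4.0)
        trial = generate_task_schedule("S01", "tRelaxed", cfg)[0]
        ev = simulate_stroke(trial, cfg)
        x = ev["x_mm"].to_numpy() - ev["x_mm"].iloc[0]
        assert x.max() > x[-1] * 1.05

    def test_overdamped_truth_rejected(self):
        with pytest.raises(ValueError, match="underdamped"):
            MSDTruth(1.2, 8.0)

    def test_axes_realise_area_distribution(self, default_config):
        sched = generate_task_schedule("S01", "tRelaxed", default_config)
        areas = []
        for i, tr in enumerate(sched[:30]):
            ev = simulate_stroke(tr, default_config, np.random.default_rng(i))
            areas.append(np.pi * (ev["major_mm"] * ev["minor_mm"]).mean())
        assert 180 < np.mean(areas) < 380  # around the configured raw scale

    def test_jittered_interval_mean(self, default_config):
        from trackstress.synthetic_data import _sample_intervals
        iv = _sample_intervals(100_000, default_config, np.random.default_rng(0))
        assert iv.mean() * 1000 == pytest.approx(8.17, abs=0.05)
        assert iv.min() > 0


class TestArtifacts:
    def _events(self, seed=0):
        cfg = GeneratorConfig(seed=seed)
        trial = generate_task_schedule("S01", "tRelaxed", cfg)[0]
        return simulate_stroke(trial, cfg, np.random.default_rng(seed)), cfg

    def test_probability_zero_is_identity(self):
        ev, cfg = self._events()
        cfg0 = GeneratorConfig(**{**cfg.__dict__, "gap_probability": 0.0})
        out = inject_artifacts(ev, cfg0, np.random.default_rng(0))
        pd.testing.assert_frame_equal(out, ev)

    def test_probability_one_always_discontinuous(self):
        ev, cfg = self._events()
        cfg1 = GeneratorConfig(**{**cfg.__dict__, "gap_probability": 1.0})
        for seed in range(20):
            out = inject_artifacts(ev, cfg1, np.random.default_rng(seed))
            multi_finger = out["finger_id"].nunique() > 1
            gapped = np.diff(np.sort(out["t_s"])).max() > 0.05
            assert multi_finger or gapped

    def test_largest_segment_preserves_displacement(self):
        ev, cfg = self._events(3)
        cfg1 = GeneratorConfig(**{**cfg.__dict__, "gap_probability": 1.0})
        out = inject_artifacts(ev, cfg1, np.random.default_rng(1))
        from trackstress.stroke_segmentation import SegmentationConfig, select_largest_stroke, split_strokes
        res = split_strokes(out, SegmentationConfig())
        largest = select_largest_stroke(res.strokes)
        full_extent = abs(ev["x_mm"].iloc[-1] - ev["x_mm"].iloc[0])
        assert largest.x_extent_mm > 0.3 * full_extent


class TestEDA:
    def test_zero_rate_zero_noise_flat_phasic(self):
        from trackstress.eda_processing import decompose_eda
        from trackstress.synthetic_data import EDAModel
        cfg = GeneratorConfig(eda_model=EDAModel(
            scr_rate_hz={c: 0.0 for c in CONDITIONS}, noise_sd_uS=0.0))
        s, truth = simulate_eda(120.0, "tRelaxed", cfg, np.random.default_rng(0))
        assert truth["scr_times_s"] == []
        _, phasic = decompose_eda(s)
        assert np.max(phasic) < 0.02

    def test_injected_pulse_count_recovered(self):
        from trackstress.eda_processing import count_scrs, decompose_eda, filter_eda
        from trackstress.synthetic_data import EDAModel, _scr_pulse
        cfg = GeneratorConfig(eda_model=EDAModel(
            scr_rate_hz={c: 0.0 for c in CONDITIONS}, noise_sd_uS=0.001))
        s, _ = simulate_eda(120.0, "tRelaxed", cfg, np.random.default_rng(1))
        y = s.eda_uS.copy()
        for onset in (20.0, 50.0, 80.0):
            y += 0.05 * _scr_pulse(s.t_s - onset, 0.75, 3.0)
        from trackstress.eda_processing import EDASeries
        _, phasic = decompose_eda(filter_eda(EDASeries(s.t_s, y, 4.0)))
        n, _ = count_scrs(phasic, 4.0)
        assert n == 3

    def test_stressed_tonic_strictly_higher_in_expectation(self):
        cfg = GeneratorConfig(seed=0)
        means = {c: [] for c in CONDITIONS}
        for seed in range(20):
            for c in CONDITIONS:
                s, _ = simulate_eda(100.0, c, cfg, np.random.default_rng(seed))
                means[c].append(s.eda_uS.mean())
        assert np.mean(means["tStressed"]) > np.mean(means["tRelaxed"])


class TestSelfReports:
    def test_all_markers_present_and_in_range(self, default_config):
        df = simulate_self_reports("S01", "Relax-Stress", default_config)
        assert list(df["marker"]) == list(SR_MARKERS)
        for col in ("stress", "tension", "concentration"):
            assert df[col].between(0, 10).all()

    def test_stressed_phase_elevated(self, default_config):
        vals = {m: [] for m in SR_MARKERS}
        for sid in (f"X{i}" for i in range(40)):
            df = simulate_self_reports(sid, "Relax-Stress", default_config).set_index("marker")
            for m in SR_MARKERS:
                vals[m].append(df.loc[m, "stress"])
        # SR4 follows the stressor (mean 6.22); SR1 ends relaxation (2.27)
        assert np.mean(vals["SR4"]) > np.mean(vals["SR1"]) + 2.0


class TestStudy:
    def test_shape(self, small_study):
        assert len(small_study.subjects) == 6
        subj = small_study.subjects[0]
        total = sum(len(subj.conditions[c].schedule) for c in CONDITIONS)
        assert total == 240
        for c in CONDITIONS:
            assert len(subj.conditions[c].annotations) == 120

    def test_arm_counts_default_proportion(self):
        cfg = GeneratorConfig(n_subjects=18)
        arms = [arm_of(s, cfg) for s in subject_ids(cfg)]
        assert arms.count("Relax-Stress") == 8 and arms.count("Stress-Relax") == 10

    def test_arm_assignment_override(self):
        cfg = GeneratorConfig(n_subjects=4, arm_assignment={"S01": "Stress-Relax"})
        assert arm_of("S01", cfg) == "Stress-Relax"

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_study(GeneratorConfig(n_subjects=1))

    def test_same_seed_reproduces_exactly(self):
        a = simulate_study(GeneratorConfig(n_subjects=2, seed=13))
        b = simulate_study(GeneratorConfig(n_subjects=2, seed=13))
        for sa, sb in zip(a.subjects, b.subjects):
            pd.testing.assert_frame_equal(sa.self_reports, sb.self_reports)
            for c in CONDITIONS:
                pd.testing.assert_frame_equal(sa.conditions[c].events, sb.conditions[c].events)
                assert np.array_equal(sa.conditions[c].eda.eda_uS, sb.conditions[c].eda.eda_uS)


def test_configured_area_effect_recovered_by_cohens_d():
    """A configured standardized area effect reappears in the measured
    condition-level contact-area means (many subjects, few trials each)."""
    from trackstress.stats_analysis import cohens_d
    from trackstress.synthetic_data import EffectSpec, _subject_area_params

    d_true = 0.6
    cfg = GeneratorConfig(seed=21, effect_spec=EffectSpec(d_area_mean=d_true))
    relaxed, stressed = [], []
    for i in range(1000):
        sid = f"S{i + 1:02d}"
        m_r, _ = _subject_area_params(sid, "tRelaxed", "click", cfg)
        m_s, _ = _subject_area_params(sid, "tStressed", "click", cfg)
        relaxed.append(m_r)
        stressed.append(m_s)
    d_hat, _ = cohens_d(relaxed, stressed)
    assert d_hat == pytest.approx(d_true, abs=0.15)
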