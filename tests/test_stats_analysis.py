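"""Routing, normalization, effect sizes, power, ANOVA, subsets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trackstress.stats_analysis import (
    DegenerateDataError, PAIRED_T, WILCOXON, bonferroni_alpha, cohens_d,
    correlate, during_phase_value, effect_band, format_alpha, minmax_normalize,
    order_condition_anova, paired_compare, power_paired_t, subset_decimated,
    subset_initial,
)


class TestNormalization:
    def test_four_phase_values(self):
        # raw end-of-phase stress means 2.27 / 3.78 / 6.22 / 4.50
        out = minmax_normalize([2.27, 3.78, 6.22, 4.50])
        assert np.allclose(out, [0.0, 0.3823, 1.0, 0.5646], atol=5e-5)

    def test_already_unit_range_unchanged(self):
        assert np.allclose(minmax_normalize([0.0, 1.0]), [0.0, 1.0])

    def test_order_preserved(self):
        v = [1.0, 2.5, 4.0, 9.0]
        assert np.all(np.diff(minmax_normalize(v)) > 0)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateDataError):
            minmax_normalize([3.0, 3.0, 3.0, 3.0])

    def test_during_phase_is_marker_mean(self):
        assert during_phase_value(2.0, 4.0) == 3.0
        assert during_phase_value(5.0, 5.0) == 5.0
        with pytest.raises(ValueError):
            during_phase_value(2.0, float("nan"))


class TestEffectSize:
    def test_pooled_sd_reproduces_published_style_value(self):
        # means 0.40/0.55 with SDs 0.18/0.16 -> d ~ 0.88 (prints as 0.87-0.88)
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.normal(0.40, 0.18, n)
        y = rng.normal(0.55, 0.16, n)
        d, band = cohens_d(x, y)
        assert d == pytest.approx(0.881, abs=0.05)
        assert band == "large"

    @pytest.mark.parametrize("d,band", [
        (0.10, "negligible"), (0.35, "small"), (0.76, "medium"), (0.92, "large"),
        (-0.85, "large"),
    ])
    def test_bands(self, d, band):
        assert effect_band(d) == band

    def test_identical_vectors_error(self):
        with pytest.raises(DegenerateDataError):
            cohens_d([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestPower:
    def test_published_power_points(self):
        # one-tailed alpha=.05, n=18 pairs
        assert round(power_paired_t(0.73, 18) * 100) == 91
        assert round(power_paired_t(0.44, 18) * 100) == 56
        assert power_paired_t(0.87, 18) >= 0.97

    def test_saturation(self):
        assert power_paired_t(5.0, 18) == pytest.approx(1.0, abs=1e-9)

    def test_two_tailed_less_powerful(self):
        assert power_paired_t(0.5, 18, tails=2) < power_paired_t(0.5, 18, tails=1)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(42)
        n, reps = 18, 8000
        crit = sps.t.ppf(0.95, n - 1)
        for dz in (0.2, 0.73, 1.2):
            diffs = rng.normal(dz, 1.0, size=(reps, n))
            tstat = diffs.mean(1) / (diffs.std(1, ddof=1) / np.sqrt(n))
            emp = float(np.mean(tstat > crit))
            assert emp == pytest.approx(power_paired_t(dz, n), abs=0.015)


class TestRouting:
    def test_normal_differences_route_mostly_to_t(self):
        rng = np.random.default_rng(1)
        routes = []
        for _ in range(400):
            x = rng.normal(0, 1, 18)
            y = x + rng.normal(1, 1, 18)
            routes.append(paired_compare(x, y).test_name)
        frac_t = np.mean([r == PAIRED_T for r in routes])
        assert frac_t == pytest.approx(0.95, abs=0.04)  # Shapiro type-I ~ 5%

    def test_heavy_tailed_differences_route_to_wilcoxon(self):
        rng = np.random.default_rng(2)
        routes = []
        for _ in range(200):
            x = rng.normal(0, 1, 18)
            y = x + rng.standard_cauchy(18)
            routes.append(paired_compare(x, y).test_name)
        assert np.mean([r == WILCOXON for r in routes]) > 0.8

    def test_clear_separation_tiny_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 18)
        y = x + 5.0 + rng.normal(0, 0.01, 18)
        assert paired_compare(x, y).p_value < 1e-3

    def test_routing_invariant_under_affine_rescale(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(10, 2, 18)
            y = x + rng.normal(0.5, 1, 18)
            r1 = paired_compare(x, y)
            r2 = paired_compare(3.7 * x + 11, 3.7 * y + 11)
            assert r1.test_name == r2.test_name
            assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6)

    def test_all_zero_differences_error(self):
        v = np.arange(6.0)
        with pytest.raises(DegenerateDataError):
            paired_compare(v, v)


class TestCorrelation:
    def test_perfect_linear(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        assert correlate(x, x).coefficient == pytest.approx(1.0)
        assert correlate(x, -x).coefficient == pytest.approx(-1.0)

    def test_monotone_nonlinear_prefers_spearman(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(1.0, 40)  # non-normal -> Spearman route
        y = np.exp(3 * x)
        res = correlate(x, y)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_constant_vector_error(self):
        with pytest.raises(DegenerateDataError):
            correlate(np.ones(10), np.arange(10.0))


class TestAnova:
    def _long(self, n_per_arm, effect_by_arm, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for arm, eff in effect_by_arm.items():
            for i in range(n_per_arm):
                sid = f"{arm}{i}"
                base = rng.normal(0, 1)
                rows.append({"subject_id": sid, "order_arm": arm,
                             "condition": "tRelaxed", "value": base + rng.normal(0, 0.3)})
                rows.append({"subject_id": sid, "order_arm": arm,
                             "condition": "tStressed", "value": base + eff + rng.normal(0, 0.3)})
        return pd.DataFrame(rows)

    def test_df_match_cell_means_layout(self):
        res = order_condition_anova(self._long(9, {"A": 1.0, "B": 1.0}))
        assert (res.df1, res.df2) == (1, 32)  # 2n - 4 at n = 18

    def test_equal_effects_give_null_interaction(self):
        ps = [order_condition_anova(self._long(9, {"A": 1.0, "B": 1.0}, seed=s)).p
              for s in range(30)]
        assert np.mean(np.asarray(ps) < 0.05) < 0.2

    def test_arm_specific_effect_detected_at_large_n(self):
        res = order_condition_anova(self._long(150, {"A": 0.0, "B": 1.0}, seed=1))
        assert res.p < 0.05

    def test_single_subject_arm_rejected(self):
        df = self._long(2, {"A": 1.0, "B": 1.0})
        df = df[~((df.order_arm == "B") & (df.subject_id == "B1"))]
        with pytest.raises(ValueError, match="at least 2"):
            order_condition_anova(df)


class TestSubsets:
    def test_initial_ten_percent_of_forty(self):
        assert subset_initial(list(range(40)), 0.10) == [0, 1, 2, 3]

    def test_fraction_one_keeps_all(self):
        assert subset_initial(list(range(7)), 1.0) == list(range(7))

    def test_ten_trials_keep_one(self):
        assert subset_initial(list(range(10)), 0.10) == [0]

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            subset_initial(list(range(10)), 0.0)

    def test_decimated_keeps_ends_plus_two(self):
        out = subset_decimated(list(range(40)), 7)
        assert len(out) == 4 and 0 in out and 39 in out
        assert all(0 <= v <= 39 for v in out)

    def test_decimated_n4_forced(self):
        assert sorted(subset_decimated(list(range(4)), 0)) == [0, 1, 2, 3]

    def test_decimated_deterministic_per_seed(self):
        assert subset_decimated(list(range(40)), 3) == subset_decimated(list(range(40)), 3)

    def test_decimated_needs_four(self):
        with pytest.raises(ValueError):
            subset_decimated([1, 2, 3], 0)


class TestBonferroni:
    def test_three_model_threshold(self):
        alpha = bonferroni_alpha(0.05, 3)
        assert alpha == pytest.approx(0.0166667, abs=1e-6)
        assert format_alpha(alpha) == "0.017"

    def test_single_comparison_unchanged(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_monotone_in_m(self):
        vals = [bonferroni_alpha(0.05, m) for m in range(1, 8)]
        assert vals == sorted(vals, reverse=True)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
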