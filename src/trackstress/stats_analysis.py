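"""Paired-comparison protocol: normalization, test routing, effects, power.

The study design is within-subject: every subject contributes one value per
condition (relaxed vs stressed), so comparisons are paired and one-tailed in
the direction physiology predicts.  Routing follows normality of the paired
differences (Shapiro-Wilk at alpha = .05): normal -> paired t test,
otherwise Wilcoxon signed-rank.  Effect size is Cohen's d with the pooled
across-condition SD, banded as negligible (<0.20), small (0.20-0.49),
medium (0.50-0.79) or large (>=0.80).  Post hoc power uses the noncentral
t distribution with noncentrality d*sqrt(n).  Sensitivity subsets (initial
10%, first/last + 2 random "decimated" trials) and the Order x Condition
interaction ANOVA complete the protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SHAPIRO_ALPHA = 0.05

PAIRED_T = "paired_t"
WILCOXON = "wilcoxon_signed_rank"

EFFECT_BANDS = ((0.20, "negligible"), (0.50, "small"), (0.80, "medium"))


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class StatTestResult:
    test_name: str
    statistic: float
    p_value: float  # one-tailed unless requested otherwise
    n: int
    cohens_d: float
    effect_band: str
    power_beta: float
    shapiro_p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Per-subject min-max scaling of a phase vector to [0, 1].

    Applied across the experimental phases of one subject so that
    between-subject scale-use differences do not dominate the comparison.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        raise DegenerateDataError("degenerate normalization: all phase values equal")
    return (v - lo) / (hi - lo)


def during_phase_value(before: float, after: float) -> float:
    """Self-report value *during* a phase: mean of its bracketing markers."""
    if before is None or after is None or not (np.isfinite(before) and np.isfinite(after)):
        raise ValueError("both bracketing self-report markers are required")
    return (before + after) / 2.0


def effect_band(d: float) -> str:
    mag = abs(d)
    for cut, name in EFFECT_BANDS:
        if mag < cut:
            return name
    return "large"


def cohens_d(x, y):
    """Cohen's d with the pooled SD of the two condition vectors (d_av).

    d = (mean(y) - mean(x)) / sqrt((sd_x^2 + sd_y^2) / 2).  Positive d means
    y (by convention the stressed condition) exceeds x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("cohens_d needs n >= 2 per condition")
    pooled = math.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    if pooled == 0.0:
        raise DegenerateDataError("zero pooled SD")
    d = float((y.mean() - x.mean()) / pooled)
    return d, effect_band(d)


def power_paired_t(dz: float, n: int, alpha: float = 0.05, tails: int = 1) -> float:
    """Power of a paired t test at effect size dz with n pairs.

    Noncentral t with df = n-1 and noncentrality dz*sqrt(n); critical value
    from the central t at the one- or two-tailed alpha.
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 1
    delta = dz * math.sqrt(n)
    if tails == 1:
        crit = stats.t.ppf(1 - alpha, df)
        return float(1 - stats.nct.cdf(crit, df, delta))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(crit, df, delta) + stats.nct.cdf(-crit, df, delta))


def paired_compare(x, y, alternative: str = "greater") -> StatTestResult:
    """Routed one-tailed paired comparison of condition vectors x and y.

    Shapiro-Wilk on the paired differences routes to the paired t test
    (differences normal) or the Wilcoxon signed-rank test.  ``alternative``
    is the direction of y - x ("greater": y expected larger).  Wilcoxon uses
    the exact null distribution for n < 10 (no ties) and the normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 5:
        raise ValueError("paired_compare needs n >= 5 pairs")
    diff = y - x
    if np.all(diff == 0):
        raise DegenerateDataError("all paired differences are zero")
    if np.ptp(diff) == 0:
        # constant nonzero shift: normality undefined; a t test is exact here
        sw_p = 1.0
    else:
        sw_p = float(stats.shapiro(diff).pvalue)
    d, band = cohens_d(x, y)
    power = power_paired_t(abs(d), n, SHAPIRO_ALPHA, tails=1)
    if sw_p > SHAPIRO_ALPHA:
        res = stats.ttest_rel(y, x, alternative=alternative)
        return StatTestResult(PAIRED_T, float(res.statistic), float(res.pvalue),
                              n, d, band, power, sw_p)
    nz = diff[diff != 0]
    method = "exact" if (nz.size < 10 and np.unique(np.abs(nz)).size == nz.size) else "approx"
    res = stats.wilcoxon(y, x, alternative=alternative, correction=True, method=method)
    return StatTestResult(WILCOXON, float(res.statistic), float(res.pvalue),
                          n, d, band, power, sw_p)


def correlate(x, y) -> CorrelationResult:
    """Pearson when both vectors pass Shapiro-Wilk normality, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("correlate needs equal-length vectors of n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector")
    normal = (stats.shapiro(x).pvalue > SHAPIRO_ALPHA and
              stats.shapiro(y).pvalue > SHAPIRO_ALPHA)
    if normal:
        r, p = stats.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), float(p))
    r, p = stats.spearmanr(x, y)
    return CorrelationResult("spearman", float(r), float(p))


def order_condition_anova(values: pd.DataFrame) -> AnovaResult:
    """Order x Condition interaction F test.

    ``values`` must be long-format with columns subject_id, order_arm,
    condition, value: one row per subject per condition.  The interaction is
    tested with a two-way ANOVA on the 2n condition-level observations
    (error df = 2n - 4; e.g. df (1, 32) at n = 18), asking whether the
    condition effect differs between the counterbalancing arms.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    required = {"subject_id", "order_arm", "condition", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"need columns {sorted(required)}")
    counts = values.groupby("order_arm")["subject_id"].nunique()
    if len(counts) != 2 or (counts < 2).any():
        raise ValueError("each counterbalancing arm needs at least 2 subjects")
    per = values.groupby("subject_id")["condition"].nunique()
    if (per != 2).any():
        raise ValueError("every subject needs exactly one value per condition")
    model = ols("value ~ C(order_arm) * C(condition)", data=values).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(order_arm):C(condition)"]
    return AnovaResult(float(row["F"]), int(row["df"]),
                       int(table.loc["Residual", "df"]), float(row["PR(>F)"]))


def subset_initial(trials: Sequence, fraction: float = 0.10) -> list:
    """The initial ``fraction`` of trials in production order (10% of a
    40-trial block = the 4 trials closest to the stressor)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    trials = list(trials)
    k = int(round(fraction * len(trials)))
    return trials[:max(k, 1)] if trials else []


def subset_decimated(trials: Sequence, rng: np.random.Generator | int) -> list:
    """Low-production-rate subset: the first, the last, and 2 random interior
    trials (size exactly 4), emulating sparse click arrival in the wild."""
    trials = list(trials)
    n = len(trials)
    if n < 4:
        raise ValueError("subset_decimated needs at least 4 trials")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    interior = rng.choice(np.arange(1, n - 1), size=2, replace=False)
    idx = sorted({0, n - 1, *map(int, interior)})
    return [trials[i] for i in idx]


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison threshold family_alpha / m (display-round to 3 decimals
    with :func:`format_alpha`; comparisons use the exact value)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def format_alpha(alpha: float) -> str:
    return f"{alpha:.3f}"
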