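# trackstress

Detecting **acute stress from laptop-trackpad finger dynamics**.

Stress raises muscle tension and motor-control variability in the hand and
forearm. When someone uses a trackpad under stress, that shows up in how the
fingertip meets the pad — a larger and more variable contact patch — and,
potentially, in the dynamics of the pointing strokes themselves. This package
implements the full analysis pipeline for a counterbalanced within-subject
study of this effect (relaxed vs. stressed task phases, three pointing-task
types over a Fitts-style distance-by-width grid), together with a synthetic
study generator so every stage can be verified against known ground truth.
It is aimed at researchers in digital biomarkers, affective computing and
HCI who want a tested, reproducible reference implementation.

## What it computes

**Mass-spring-damper (MSD) stroke model.** A goal-directed stroke toward a
target approximates the step response of a second-order system. For an
underdamped system with damping ratio Γ ∈ (0, 1) and damped frequency
ω (rad/s),

```
x(t) = D·[1 − e^(−Γωₙt)(cos ωt + (Γωₙ/ω)·sin ωt)],   ωₙ = ω/√(1−Γ²)
```

After resampling the largest continuous stroke onto a uniform grid and
removing the steady-state level, the residual is a decaying sinusoid — an
exact AR(2) signal. A least-squares (covariance / LPC) fit
`x[n] = a₁x[n−1] + a₂x[n−2] + e[n]` yields a complex pole pair
`z = r·e^(±iθ)`; mapping to continuous time, `s = (ln r ± iθ)/dt`, gives
`Γ = −Re(s)/|s|` and `ω = θ/dt`.

**Stroke segmentation.** Trackpad users lift and switch fingers mid-trial,
so trial logs contain gaps and concurrent traces. Events are partitioned by
finger id and cut at large time gaps or coordinate jumps; the stroke with
the greatest net horizontal extent is the MSD fitting target, while *all*
strokes and substrokes contribute to the finger-dynamics metrics.

**Finger-dynamics metrics.** Contact area π·a·b from the logger's ellipse
axes, and velocity/acceleration by finite-differencing the horizontal
position. Per-trial values average over strokes; phase values average over
each task type's 40 trials and then (unweighted) over the three task types
("Mixed-Task" level).

**Statistical protocol.** Min-max per-subject normalization; Shapiro-Wilk
routing between one-tailed paired *t* and Wilcoxon signed-rank tests;
Cohen's *d* with pooled across-condition SD (bands: <0.20 negligible,
0.20–0.49 small, 0.50–0.79 medium, ≥0.80 large); post hoc power from the
noncentral *t* distribution (δ = d·√n); Bonferroni 0.05/3 for the
task-specific models; Order × Condition interaction ANOVA; and sensitivity
subsets (initial 10% of click trials, and a first/last + 2-random
"decimated" subset).

**EDA stressor validation.** Skin conductance is screened for quality,
low-pass filtered (zero-phase 6th-order Butterworth at 1 Hz), split into
tonic baseline and phasic component, and summarised per phase as tonic
mean, phasic mean and the count of skin-conductance responses (phasic peaks
with prominence ≥ 0.01 µS).

## Worked example

```python
from trackstress import power_paired_t
from trackstress.pipeline import analyze_study
from trackstress.synthetic_data import GeneratorConfig, simulate_study

# analytic post hoc power of a one-tailed paired t test, n=18 pairs
print(round(power_paired_t(0.73, 18) * 100, 1))   # 90.7  -> prints as 91%
print(round(power_paired_t(0.44, 18) * 100, 1))   # 55.8  -> prints as 56%

# a small synthetic study, analysed end to end
study = simulate_study(GeneratorConfig(n_subjects=6, seed=11))
report = analyze_study(study)

print(round(report["gap_fraction_mean"], 3))      # 0.402 (38% configured)
area = report["mixed_task"]["normalized_mean_area_mm2"]
print(area["test_name"], round(area["p_value"], 4))   # paired_t 0.0066
init = report["sensitivity"]["initial_10pct"]["mean_area_mm2"]
print({k: round(v, 1) for k, v in init["means"].items()})
# {'tRelaxed': 280.1, 'tStressed': 297.4}  raw click areas, first 4 trials
```

The report says: about 40% of trials contained a stroke gap (matching the
configured rate); the mixed-task mean contact area is significantly higher
under stress (one-tailed paired *t*, p ≈ .007 at n=6); and the effect is
already visible in the first four click trials of each phase (raw means
280 vs 297 mm²). The MSD parameters Γ and ω show no condition difference
(the generator's ground-truth dynamics barely differ between conditions).

A CLI wraps the same stages:

```sh
trackstress run-all --seed 11 --out out/        # simulate + metrics + analyze
trackstress simulate --seed 11 --out study/     # just the synthetic study CSVs
```

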