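# Methods

## The measurement problem

The pipeline decides, from passively logged trackpad interaction, whether a
person was acutely stressed while performing pointing tasks. Two families
of biomechanical markers are computed per trial and compared between a
relaxed and a stressed task phase of the same subject:

* **Second-order stroke dynamics** — the damping ratio Γ and damped
  frequency ω of a mass-spring-damper (MSD) approximation to the pointing
  stroke. Muscle co-contraction under stress plausibly stiffens the
  effective limb system and shifts these parameters.
* **Contact-patch and kinematic summaries** — mean and SD of the
  contact-ellipse area under the fingertip, and of the horizontal velocity
  and acceleration. Higher force production and motor variability under
  stress enlarge the mean and spread of the contact patch.

Self-reports (0–10 stress/tension/concentration at six markers) and wrist
electrodermal activity (EDA) validate that the stressor worked.

## Stroke model and identification

An underdamped step response

x(t) = D·[1 − e^(−Γωₙt)(cos ωt + (Γωₙ/ω) sin ωt)], with ωₙ = ω/√(1−Γ²),

is identified through its sampled form: after removing the steady state,
x[n] obeys the recurrence x[n] = a₁x[n−1] + a₂x[n−2] exactly, with poles
z = e^{(−Γωₙ ± iω)Δt}. The estimation chain is:

1. **Largest stroke** — the segmentation unit with the greatest net
   |x_end − x_start| (ties: longer time span, then earlier start). The
   x-direction carries the task displacement; y is not modelled.
2. **Uniform resampling** — linear interpolation onto a 10 ms grid. The
   logger samples at jittered ~8 ms intervals; LPC needs uniform sampling.
3. **Steady-state removal** — the mean of the final 10% of grid samples is
   subtracted (not the series mean: a noise-free step response is then an
   *exact* AR(2) signal, which the series mean would not give).
4. **Tail truncation** — samples after the residual last reaches 2% of its
   peak are dropped. Once the oscillation has decayed into measurement
   noise, further samples only bias the least-squares fit (noise in the
   regressors attenuates the poles toward zero). On exact data truncation
   is harmless — any trailing subsegment satisfies the same recurrence.
5. **Covariance-method AR(2) fit** — ordinary least squares on the
   one-step-ahead prediction, exact on short deterministic segments
   (the autocorrelation/windowed variant is biased there).
6. **Pole mapping** — z = r·e^(±iθ) → s = (ln r ± iθ)/Δt, Γ = −Re(s)/|s|,
   ω = θ/Δt, ωₙ = |s|. Real poles are flagged *overdamped* and |z| ≥ 1
   *unstable*; both are excluded from aggregation with counts logged,
   never coerced into the underdamped parameterisation.

Verified behaviour (computed by the test suite): noise-free strokes over
Γ ∈ {0.3…0.9} × ω ∈ {2…20} rad/s are recovered to ≤1e-4 relative error
(≤1e-6 when the sampling grid matches the analysis grid); with default
jitter and positional noise the median error is ~3%. Γ and ω are invariant
to amplitude scaling, and halving the analysis grid changes them by <1% on
noise-free input.

## Segmentation

Events are grouped by finger id, then cut wherever Δt > 50 ms or a
coordinate jumps by more than 15 mm between consecutive samples; fragments
with fewer than 4 samples are discarded (counted). A trial "has a gap" if
it produced more than one stroke or any discarded fragment. The 50 ms gap
threshold is ~6× the mean sampling interval. The 15 mm jump threshold sits
above the largest per-sample displacement a legitimate stroke can produce
(peak velocities ~0.5 m/s over ~100 mm targets × jittered ~20 ms intervals
≈ 12 mm) while remaining far below typical lift-and-reposition jumps; a
5 mm threshold would cut fast legitimate motion mid-stroke.

## Finger-dynamics metrics

Contact area is π·a·b with the logger's major/minor axes used literally,
matching how such areas are conventionally reported from this logger even
though the geometric ellipse area from full axes would be π·(a/2)·(b/2);
`axes_are_full=True` applies the /4 factor for users who want physical
units. Velocity/acceleration are signed first/second finite differences of
x(t); SDs are sample SDs over the within-stroke series (a single
acceleration sample contributes SD 0). Per-trial values are unweighted
means over all strokes and substrokes; the alternative (pooling all samples
of a trial before taking the SD) is not implemented. Phase aggregation is
two-stage: per-task-type mean over valid trials, then the unweighted mean
of the three task-type values — deliberately *not* the pooled trial mean,
so task types with different numbers of valid trials carry equal weight.

For the study-level comparison, each finger-dynamics measure is min-max
normalized per subject across its six task-type × condition cells before
averaging to the Mixed-Task level. Normalizing across only the two phase
values would force every subject to 0 and 1 and destroy the comparison;
the six-cell scheme preserves the condition contrast while absorbing
between-subject scale differences. Γ and ω stay on their native scales.

## EDA processing

Zero-phase (forward–backward) 6th-order Butterworth low-pass at 1 Hz, so
SCR peak latencies are not shifted. Quality screening excludes recordings
with no signal (range < 0.01 µS), any sample above 20 µS, or >5% noisy
5-second epochs (an epoch is noisy if any sample-to-sample jump exceeds
1 µS or any value leaves [0.01, 20] µS — a deterministic rule-based screen,
with all thresholds configurable).

The tonic/phasic split is a sliding-window low-percentile baseline: 10th
percentile over a centred 10 s window, smoothed by a 1 s moving average;
phasic = series − tonic, floored at 0. The unfloored phasic plus tonic
reconstructs the filtered series exactly, and the baseline is
offset-equivariant. This is a deterministic, dependency-free decomposition,
*not* a deconvolution of sudomotor nerve activity: absolute tonic/phasic
values are comparable within this pipeline but not to deconvolution-based
analyses. SCRs are counted as phasic local maxima with prominence
≥ 0.01 µS and ≥ 1 s separation; the count is monotone non-increasing in
the threshold.

## Statistical protocol

* **Routing** — Shapiro-Wilk at α = .05 on the *paired differences*
  (the marginals are an alternative the routing rule does not use):
  non-significant → one-tailed paired *t*; otherwise one-tailed Wilcoxon
  signed-rank (exact null for n < 10 without ties, normal approximation
  with continuity correction above). One-tailed because the direction of
  every effect is predicted in advance.
* **Effect size** — Cohen's d with the pooled across-condition SD
  (d_av = (m_y − m_x)/√((s_x²+s_y²)/2)). This is the definition consistent
  with reporting condition means and SDs side by side; the paired
  dz = t/√n is generally larger and is *not* what the effect bands refer
  to. Bands: <0.20 negligible, 0.20–0.49 small, 0.50–0.79 medium, ≥0.80
  large.
* **Power** — noncentral t with df = n−1 and δ = d·√n at one-tailed
  α = .05. At n = 18 this gives 55.8% for d = 0.44, 90.7% for d = 0.73 and
  97.1% for d = 0.87 (the suite cross-checks these against a Monte-Carlo
  oracle to within 1.5 points).
* **Order × Condition ANOVA** — a two-way ANOVA on the 2n condition-level
  observations (cell-means layout), giving interaction df (1, 2n−4) —
  (1, 32) at n = 18. The textbook mixed-model would use df (1, n−2); the
  cell-means layout is used so interaction F statistics are directly
  comparable with studies that report df₂ = 32 at n = 18.
* **Multiplicity** — Bonferroni 0.05/3 (displayed 0.017, compared exactly)
  for the three task-specific models.
* **Sensitivity** — the initial 10% of click trials in production order
  (4 of 40), and a "decimated" subset of {first, last, two seeded random
  interior trials}, both on raw mm² values.
* **Self-reports** — the value *during* a phase is the mean of its
  bracketing markers; each scale is min-max normalized per subject across
  the four phases (all-equal subjects are flagged out). Marker↔phase
  bracketing per counterbalancing arm: in the Relax-Stress arm the
  stressed-task phase is bracketed by SR4 and SR5, in the Stress-Relax arm
  by SR1 and SR2, with SR0/SR3 taken at baselines.

Calibration computed by the suite: type-I error of the routed comparison is
≈5% on null data (2,500 replicates), and empirical power matches the
analytic value within 3 points at d ∈ {0.44, 0.73} (2,000 replicates each).

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes. Defaults:

| parameter | default | basis |
|---|---|---|
| subjects / arms | 18, split 8 Relax-Stress / 10 Stress-Relax | study design |
| trials per condition | 120 = 3 task types × 20 (D,W) configs × 2 reps | task grid |
| sampling interval | truncated normal, mean 8.17 ms, SD 3.75 ms | logger rate |
| gap probability | 0.38 per trial | observed gap prevalence |
| true dynamics | Γ 0.538/0.540, ω 8.0/8.2 rad/s (relaxed/stressed) | see below |
| click contact area | 270.9 / 284.6 mm² (relaxed/stressed), within-trial SD 16.7 / 21.2 | raw click-trial anchors |
| between-subject area SD | 26.7 mm² (≙ SE 6.3 at n=18) | same anchors |
| EDA | 4 Hz; tonic 2.057 / 4.223 µS; SCR rate 0.099 / 0.167 s⁻¹; biexponential pulses (rise 0.75 s, decay 3 s); noise SD 0.003 µS | task-phase EDA summaries; Empatica-class sensor rate |
| self-report stress, end of phase | 2.27 / 3.78 / 6.22 / 4.50 (Relaxation / tRelaxed / Stressor / tStressed) | phase-mean anchors |

Design choices where the underlying study leaves the distribution open:

* Sampling jitter is a lower-truncated normal with the location corrected
  (Mills-ratio fixed point) so the truncated mean equals 8.17 ms exactly.
* Gaps remove a 50–300 ms span uniformly placed in the middle 80% of the
  trial and relabel the remainder with a new finger id (a lift and
  re-placement); 30% of gapped trials also get a short, nearly stationary
  concurrent second-finger trace.
* Contact axes: per-sample areas are lognormal with the configured
  mean/SD, split into major/minor by a lognormal aspect ratio (≥1.02), so
  π·a·b reproduces the area exactly and axes stay positive and ordered.
  Subject, task-type and condition offsets are layered so that paired
  differences have nonzero variance and the six-cell normalization has a
  nondegenerate range.
* Stressed-condition dynamics differ only marginally from relaxed
  (Γ 0.538→0.540) — the generator reproduces the *absence* of an MSD
  condition effect, so a correct analysis should find Γ/ω
  non-significant. The physical ω ≈ 8 rad/s is chosen so strokes settle in
  ~1 s; sub-1 rad/s values would be incompatible with ~2 s goal-directed
  strokes.
* Step amplitude is capped so the overshooting trajectory stays on the
  140 × 70 mm pad (Γ and ω are amplitude-invariant, so this never affects
  recovery); trials take ~1.8 s plus a 1.5 s inter-trial interval,
  giving ~6.5-minute phases and ~3.3 s per click.
* SCR generation uses a 3 s refractory plus exponential waiting time with
  the rate corrected so the *effective* event rate matches the configured
  value; EDA noise SD (0.003 µS) is set so the fixed 0.01 µS detection
  threshold lies above 3σ of sensor noise, as it does for real filtered
  wrist EDA.
* Self-report markers are integer-rounded truncated normals (SD 1.2)
  around the arm-specific end-of-phase means.

What the generator does **not** emulate: learning/fatigue trends across
trials, task-difficulty (Fitts) dependence of stroke duration, vertical
task variants, pressure/capacitance channels, EDA motion artifacts, or
realistic between-subject heterogeneity in stroke dynamics (all subjects
share the condition-level Γ/ω truth). Passing tests therefore demonstrate
correctness of the *pipeline* under the stated statistical structure, not
that real trackpad data would show these effects.

## Problem sizes

The test suite and acceptance script use: 16-point (Γ, ω) recovery grids
with 6 noisy trials each; 10,000 trials for gap-rate calibration (binomial
SE ≈ 0.5 points at p = 0.38); 2,500/2,000 replicates for type-I/power
calibration; 12,000 replicates for the Monte-Carlo power oracle (SE ≈ 0.5
points); 12 × 400 s EDA phases for SCR recovery; and an 18-subject default
study for the end-to-end analysis. A 6-subject study backs the quicker
end-to-end tests.

## Known limitations

* The AR(2) fit assumes one dominant second-order mode; corrective
  submovements violate this and surface as larger residual RMS rather than
  as a model-order test.
* The percentile-baseline EDA decomposition lets very steep tonic drifts
  leak into the phasic component (≈ slope × 4.5 s); with the default drift
  (0.15 µS over a 10-minute period) the leak stays below the SCR
  threshold, but pathological recordings should be screened first.
* Wilcoxon p-values with heavy ties fall back to the normal approximation;
  exact small-sample behaviour is only guaranteed without ties.
* `subset_initial` uses production order as recorded; if trials were
  reordered post hoc the "closest to the stressor" interpretation breaks.
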