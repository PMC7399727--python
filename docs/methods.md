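# Methods

This note documents the models, estimators and numerical choices behind
`rkt`, and what the synthetic data can and cannot establish.

## Curve family

The generator models one test cycle's load-deformation curve as a strictly
monotone function of axial rotation. With u = θ − c (degrees from the curve
centre c) and torque in N·m:

    τ(u) = k_p·u + A_ir·(e^{β·max(0, u−h)} − 1) − A_er·(e^{β·max(0, −u−h)} − 1)

* **k_p** — play-region slope (default 0.08 N·m/deg). Inside the play
  region the joint offers little resistance; the slope must stay below the
  turning-point threshold.
* **h** — half-width of the play region (deg), solved during calibration.
* **A_er, A_ir** — stiffening amplitudes (N·m) per side, solved during
  calibration; asymmetric laxities need asymmetric amplitudes.
* **β** — stiffening rate (default 0.10 /deg), a family constant.

The family was chosen as the simplest shape with a controllable play region,
independently controllable end-region laxities, and physiological end-point
stiffening. It is C0-continuous with a slope break at the play edges; real
curves are smoother there, which is one reason the cubic-fit estimator
carries a model-mismatch bias (below).

### Turning points and the expressible envelope

A turning point is operationalized as the rotation where dτ/dθ crosses a
threshold, default 1 N·m per degree — the literal reading of "torque
changing faster than rotation". The criterion is unit-dependent (N·m vs
degrees); the threshold is exposed as a parameter everywhere.

This operationalization has a hard geometric consequence. Beyond a turning
point the slope exceeds the threshold, so the torque rise from turning point
to maximal rotation exceeds laxity × threshold. With a ±6 N·m sweep, each
side's laxity is therefore bounded by roughly 6 − k_p·h ≈ 5.5°, and in
practice (with the exponential tail) by ≈ 4.3° at a 16.6° slack. Feature
combinations outside this *expressible envelope* admit no curve in the
family; `calibrate_curve_params` raises a diagnostic error, and cohort
simulation rejects and redraws subject blocks whose draws fall outside it
(`make_feasibility_check`, margin 0.15°). Published laxity means for this
kind of test (5–6°) exceed the envelope — consistent with such values being
properties of a smoothing fit rather than literal unity-slope crossings of
the raw curve — so the generator's default laxity means (2.6°/2.8°) sit
inside the envelope instead. A small slack floor also exists: small laxities
imply wide sub-threshold approach regions that the slack must accommodate.

### Calibration

Given target slack, laxities and zero-torque rotation, calibration solves
for (h, A_er, A_ir) by nested Brent iterations: for each side, the distance
v\* between play edge and turning point parameterises the amplitude
A = (T_th − k_p)·e^{−β v\*}/β, and the maximal rotation solves a
linear-plus-exponential equation closed-form via the Lambert W function
(bisection fallback when the W argument would overflow). The outer iteration
adjusts h until the oracle slack matches the target; agreement is verified
to well under 0.01°.

## Protocol emulation

A trial holds seven sweeps: a lead-in external sweep, then three
internal+external pairs — four ER-directed and three IR-directed sweeps over
cycles 1–3, external first, so the final cycle contains exactly one sweep in
each direction and is the analysis cycle. Torque is sampled uniformly
(monotonically) over the ±limit range at `samples_per_sweep` points
(default 100; the real device's rate is unpublished, so this is
configurable). Rotation inverts the monotone curve on a dense 4096-point
grid; inversion error is far below sensor noise.

Per-sample Gaussian noise is added to every channel: rotation SD 0.25° and
translation SD 0.75 mm by default, half the tracker's stated static accuracy
treated as a 2-SD bound. Secondary channels are linear couplings of the
axial rotation (gains 0.03–0.15 per degree) plus noise — a deliberately
minimal stand-in for genuinely coupled joint kinematics. Hysteresis (a
torque offset of ±width/2 by sweep direction) is available but defaults to
0. A fixed +3.5° offset on the right knee's zero-torque rotation emulates a
systematic frame-setup asymmetry; it shifts positions, not slack or
laxities.

## Realized features and their variance structure

Each subject-knee-day cell's features follow

    value = μ_f + group offset + a_s + b_sk + c_sd + ε_skd

with independent Gaussian effects per feature. Default variance components
(deg²): slack 9.0/1.0/1.9/0.3, ER laxity 1.1/0.1/0.3/0.1, IR laxity
0.6/0.2/0.3/0.04 (the IR residual reconciles a printed 0.0 with a printed
3.2 % share), zero-torque rotation 4.0/1.0/1.0/0.25 (chosen; no published
decomposition exists for it). Group offsets default to the observed
female-minus-male differences (slack +2.6°, ER laxity +1.0°, IR laxity
+0.5°).

Draws with non-positive slack or laxity are rejected at the subject-block
level and redrawn (bounded retries), keeping the Gaussian interpretation
approximately intact. Two regimes matter:

* **Feature-level sampling** (`sample_feature_table`) applies only the
  positivity constraint. At laxity means ≥ 5° truncation is negligible and
  the realized variance matches the configured components; at the
  curve-feasible means (2.6°) it shrinks laxity variance by ~15–20 %.
* **Curve-level simulation** (`simulate_cohort`) additionally rejects
  envelope-infeasible blocks (~10–30 % of draws at the default scales), so
  curve-level cohorts under-disperse laxities. All variance-recovery and
  group-comparison results are therefore computed feature-level.

## Feature extraction

`compute_features` reads the maximal rotations at the torque extremes of the
sweep loading towards each extreme, takes the zero-torque rotation as the
mean of the two sweeps' linear-interpolated zero crossings, splits the curve
there, fits one least-squares cubic τ(θ) per half (≥ 8 points required), and
solves the fitted quadratic slope for the threshold crossing. Among real
roots in the fit domain with the slope increasing outward, the one nearest
the curve centre is taken. Each turning point uses the branch loading
towards its own extreme, so a hysteresis loop cannot mix branches; the
laxity/slack identities are applied at construction, making the
decomposition identity exact by construction.

Properties established against the dense numeric oracle
(`true_features`, root finding on the analytic derivative — fully
independent of the cubic fit):

* On curves sampled exactly from a cubic, the estimator is exact.
* At the default feature means the turning-point bias is ≈ 0.06°; across a
  central region (slack 14.5–18.5°, laxities 2.2–3.2°) it stays below 0.5°.
  Towards the envelope corners the elbow sharpens or flattens and the bias
  grows to ~1°; this is a property of fitting a global cubic to a
  piecewise-exponential curve, and tests assert the bound only on the
  central region.
* **Detection limit**: a laxity below ≈ 1.6° raises the slope above
  threshold by only e^{0.16} − 1 ≈ 0.17 N·m/deg. With 0.25° sensor noise
  the fitted slope then often never crosses the threshold and extraction
  fails with a turning-point error; cohort pipelines skip such trials with
  a warning. At the default laxity variances this affects roughly a quarter
  of noisy trials — an honest reflection of the estimator's limits, not a
  bug.

## Reliability and variance components

`icc_2_1` implements the two-way random-effects, absolute-agreement,
single-measurement ICC from the ANOVA mean squares (returned for audit).
Degenerate matrices with zero total variance return ICC 0 with a warning;
negative ICCs are reported as computed and only the interpretation labels
floor them. Interpretation bands: poor < 0.5 ≤ moderate < 0.75 ≤ good ≤ 0.9
< excellent (both printed boundaries assigned to "good").

Variance components come from the balanced nested ANOVA method-of-moments
solution (closed form from the stratum mean squares, after removing the
global knee means so the fixed side effect cannot leak into the strata).
On balanced data this coincides with REML — cross-checked against
statsmodels MixedLM in the tests — is unbiased, and is fast enough to run
at every point of a torque grid. Negative solutions are truncated at zero
and flagged. Incomplete subjects are dropped with a warning; a single-knee
design fixes the knee component at 0.

`pointwise_reliability` resamples every trial's analysis cycle onto a
common torque grid (default step 0.1 N·m; linear interpolation, never
extrapolating) and, at every grid point, computes the mean, the ICC(2,1) of
the subject-knee × day matrix, and the SEM as √(residual variance) of the
nested model. The two sweep directions are analysed separately and stacked.
Units missing a value at a point are dropped listwise (count reported);
points missing more than 20 % of units are flagged absent. Pooling the two
knees as units is the default; analysing sides separately amounts to
filtering the trials first.

Note on regimes: when Table-2-scale feature residuals are imposed as true
curve-level day-to-day shifts, the pointwise residual inherits them
(SEM ≈ 0.5°). The `pointwise_regime_variances` preset instead keeps
curve-level residuals near zero so the pointwise SEM is sensor-noise
dominated (≈ 0.27°), emulating devices whose feature-level residual is
largely extraction noise.

## Group comparisons

Left-vs-right uses one value per subject per knee (first test day by
default): paired t when the paired differences pass a Shapiro–Wilk gate at
α = 0.05, otherwise Wilcoxon signed-rank. Between-group comparisons analyse
each leg separately on first-day values: pooled-variance Student t when both
groups pass the gate (applied per group), otherwise Mann-Whitney U; Welch is
available by flag. Identical paired samples short-circuit to t = 0, p = 1.
The gate inflates the type-I error slightly; simulation at the study design
puts the null rejection rate near 5.5 % at nominal 5 %, monitored in the
tests rather than hidden. Post-hoc power uses the noncentral t distribution
at the observed standardized effect — a documented approximation, since the
method behind published power values of this kind is typically unstated.
`summary_ttest` reproduces a raw-data pooled t exactly from (mean, SD, n)
summaries.

## Determinism and problem sizes

All randomness flows from `numpy.random.Generator` seeds; the pipeline
derives per-stage child seeds from one run seed via `SeedSequence`, so
identical (config, seed) pairs give byte-identical artifacts. The test
suite and acceptance script use 100-replicate feature-level cohorts at the
25 × 2 × 5 design for recovery studies, 200/100 replicates for null and
detection rates, and one 25 × 2 × 5 curve-level cohort for the pointwise
analysis — sizes at which every Monte-Carlo margin in the tests is several
standard errors wide.

## Limitations

* The curve family has a slope break at the play edges and no
  viscoelastic memory; real curves show smooth transitions and hysteresis
  loops (the hysteresis parameter shifts torque but does not reproduce
  loop shape).
* Secondary channels are linear couplings; real coupled motions are
  nonlinear and subject-specific. Pointwise reliability of secondary
  channels therefore mirrors the primary channel's structure by
  construction.
* Femur motion is not modelled (no thigh-side tracking exists in the
  emulated setup).
* The expressible envelope caps laxity under the literal unity-slope
  criterion; analyses of cohorts with larger printed laxities are only
  reachable feature-level, not as simulated curves.
* Passing tests establish correctness of the estimators under the
  generator's Gaussian, balanced, independent-effects assumptions — not
  performance on real recordings with outliers, missing days or drifting
  sensor calibration.
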