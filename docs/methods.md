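# Methods

This note documents the models, estimators, numerical choices and known
limitations of `combicode`, in the order data flows through the package.

## Stimulus space

A condition is a subset of `n` stimulus elements (default `n = 5`,
labels C2, C1, B1, D1, γ); the empty subset is the catch condition. The
canonical ordering — subset size ascending, then lexicographic on sorted
element indices, catch last — is a package convention chosen for
reproducibility; nothing downstream depends on it beyond consistency. The
design matrix `X` has one row per non-catch condition with `x_ij = 1` iff
element `j` is present.

## Synthetic sessions

The generator emulates the awake five-whisker experiment and is the basis
of all validation:

| parameter | default | meaning |
|---|---|---|
| `trials_per_condition` | 20 | per condition incl. catch (640 trials) |
| `stim_duration_s` / `iti_s` | 1.0 / 2.0 s | stimulus window / inter-trial interval |
| `frame_rate_hz` | 15.45 | imaging frame rate |
| `kernel_tau_s` | 1.5 s | single-exponential calcium decay (GCaMP6s-like); rise treated as instantaneous at this frame rate |
| `baseline_f0` | 100 | somatic resting fluorescence (arbitrary units) |
| `neuropil_baseline`, `neuropil_sd` | 40, 0.5 | shared slow background + per-neuron white noise |
| `trial_noise_sd` | 0.15 | Gaussian, homoscedastic per neuron (matches the LN model's noise term) |
| run speeds | lognormal, median 30 cm/s, σ=0.3 | plus 10% slow trials (2–8 cm/s) so the running filter is exercised |

Ground-truth neurons are drawn from a mixture of three classes.
*Labeled-line* neurons have one positive weight (U(1.5, 3)) and `h = 0`;
*combination-selective* neurons have 2–3 weights drawn U(2, 3) with
`h = −Σw + U(0.3, 0.7)`, so the drive crosses threshold only when the full
member set is present — single elements evoke essentially nothing, and
supra-linear summation at the member combination follows from the convexity
of `f`. *Tabulated* neurons carry an arbitrary supplied tuning vector (for
misspecification studies). The weight ranges are chosen so that evoked
responses sit 5–15 trial-noise SDs above catch for driven conditions and
well below one SD for undriven ones, the regime the classifier assumes.

A neuron's generative tuning is its **evoked** response: the LN prediction
minus the spontaneous level `a·f(h)`. Trial amplitudes are
`tuning + N(0, σ)`, catch amplitudes pure noise. (Defining tuning as the
raw LN output instead would make every labeled-line neuron "respond" to all
31 stimuli relative to catch through its spontaneous drive `a·f(0)`, which
contradicts what the class is meant to model.)

Rendering: the per-trial ΔF/F is a boxcar over the stimulus window
convolved with the calcium kernel, implemented as an AR(1) filter with unit
steady-state gain, so a sustained stimulus saturates at its amplitude and
the discrete shape at frame `m` of the window is `1 − α^{m+1}` with
`α = exp(−1/(τ·fr))`. Averaging over the 1-s window therefore attenuates a
rendered amplitude by a known factor (≈0.28 at the defaults), which the
recovery tests account for analytically. Somatic fluorescence is
`f0·(1 + ΔF/F)`; the recorded ROI channel adds `k_true × neuropil`;
everything is clipped at 0 (never binding at the defaults).

**What the generator does not emulate:** whisk-cycle-resolved touch
dynamics, spiking discreteness, heteroscedastic or correlated trial noise,
slow drifts in responsiveness, and motion artifacts. Passing tests
demonstrate the estimators' correctness under the stated statistical
assumptions, not robustness to every property of real recordings.

## Preprocessing

- Contamination `k = min_t R(t)/N(t)` over frames with `N > ε = 1e−9`,
  clamped to [0, 1]; a negative minimum clamps to 0 with a warning; all-`N≤ε`
  neurons are flagged degenerate and passed through (`F = R`, `k = 0`).
  Note the estimator only equals the true mixing coefficient when the
  somatic signal approaches zero somewhere in the recording; under the
  synthetic defaults (somatic baseline ≫ neuropil) it clamps at 1 and the
  correction acts as a per-neuron affine offset, which catch-subtracted
  tuning analysis is invariant to. The sensitivity of the literal minimum
  (vs. a robust low quantile) is a known caveat.
- Catch-ITI baseline: `f0` is the mean of `F` over the last 1 s of the
  inter-trial interval after each catch trial, averaged across catch trials;
  `f0 ≤ 0` flags the neuron invalid. The sliding-percentile alternative
  (20th percentile, 3000-frame window) uses a centered window truncated at
  the edges; a window longer than the trace falls back to a global
  percentile with a warning.
- Quantiles everywhere (baselines, IQR, bootstrap percentiles) use linear
  interpolation between order statistics (type 7), stated because the
  median-rule and percentile results depend on it.
- Deconvolution solves `min_{e≥0} ‖dff − K e‖² + λ·Σe` (the L1 term is
  linear on the nonnegative orthant, so the problem is smooth and bound-
  constrained) with L-BFGS-B; the exponential-kernel convolution and its
  adjoint are O(T) AR(1) filters. Rates are scaled by the kernel's
  geometric sum so a train reconvolving to time-averaged ΔF/F = 1 has
  time-averaged rate 1. The default `λ = 0.01` keeps the reconvolution
  residual ≤ 20% of signal norm on default synthetic sessions (measured
  ≈3%).

## Trial statistics

The response window is `round(window_s × frame rate)` frames (half away
from zero, minimum 1; 15 frames at the defaults). Outliers are removed per
neuron × condition by the median rule (|v − median| > 2.3 × IQR) before any
analysis, and the same rule is applied to running speeds among running
trials; with fewer than 4 values the rule is skipped with a warning.
Responsiveness requires a positive raw condition mean *and* a Welch
two-sample t-test against catch surviving Benjamini–Hochberg at α = 0.05
within the neuron's 31 stimuli (the family is per neuron, not across
neurons; the variant choice — Welch — is ours, as is applying the positive-
mean clause to raw rather than catch-subtracted means; both are single-line
switches). The t-test is a vectorized Welch implementation verified exact
against `scipy.stats.ttest_ind(equal_var=False)`.

Classes: *single* = exactly one single-element stimulus significant;
*multi* = two or more; *combination* = none, but ≥1 multi-element stimulus
significant. Measured accuracy on the default generator is ~92% for both
labeled-line→single and threshold-LN→combination; the errors are chance
extra-singleton flags, whose rate is elevated because the BH step-up
threshold within a neuron is lenient when ~16 of 31 conditions are truly
active and because all conditions share one catch sample.

## Tuning, cross-validation, supra-linearity

Tuning curves are catch-subtracted means over inlier trials; CIs are
percentile bootstrap (default 1000 replicates) resampling trials with
replacement within condition, with the catch mean re-drawn per replicate.
The percentile method is slightly anticonservative at very small per-group
n (~92% coverage at n = 20, 94% at n = 50 on a Gaussian toy).

Preferred stimulus = argmax with ties to the smaller subset, then canonical
order; the principal whisker is the largest coefficient of an OLS fit of
single-trial responses on element-presence indicators plus intercept (ties
to the lower index; rank-deficiency errors name the offending element).

Partitioning is per-condition balanced (counts differ by ≤1) with a seeded
greedy swap refinement that minimizes the spread of pupil-covariate means
across parts when covariates are present (the balancing algorithm itself is
a package choice). Reliability is the Pearson correlation between partition
tuning curves; the gate is r > 0.5. In the **halves** scheme, part 0 gives
preference and part 1 is displayed; in **thirds**, parts 0–1 give the gate
and preference, and part 2 — used for nothing else — is displayed. Display
rows are normalized by their maximum absolute value.

The supra-linearity statistic is `D = LD(top) − mean_{other multi} LD`,
with the top stimulus fixed by the training partition (the test is skipped,
labelled `ns` with a reason, if that stimulus is single-element — the
average over "non-top" stimuli uses multi-element conditions only, where LD
is defined). `D` is a linear functional of the 32 test-partition condition
means, so the bootstrap resamples trials within each condition and
recombines; `p_supra` and `p_sub` are the one-sided tail fractions at
α = 0.01 each, matching a two-colour supra/sub classification. Default
10 000 replicates for single-neuron use; batch analyses use 1000–2000.

**Selection-bias note.** Under the halves scheme the reliability gate
correlates the displayed half with the training half *by selection*, which
leaks a small positive diagonal (~0.1 enrichment) into even a linear-null
population. The thirds scheme removes this entirely, which is why the
calibration studies and surrogate batteries default to it; the halves
scheme remains available and matches the display convention of the main
population figures.

## LN model and oracle

`f` is evaluated with a numerically stable split: the printed closed form
for `x > 0`, and `exp(−x²/2)·[1/√(2π) + (x/2)·erfcx(−x/√2)]` for `x ≤ 0`,
where the naive form suffers catastrophic cancellation (and can go
negative) below `x ≈ −6`. Fitting minimizes squared error on the training
tuning curve with L-BFGS-B (analytic gradient; `a ≥ 0`, `w, h` unbounded)
from an OLS-initialized start plus seeded random restarts (default 10;
`n_restarts=1` reproduces the minimal single-start procedure). The fit
target is the averaged training tuning curve, not per-trial data. R² is
`1 − SSE/SST` about the test mean and is deliberately not clipped below 0 —
negative oracle R² is how overfitting to training noise shows up. The
population comparison takes neurons with oracle test R² > 0.5 and applies a
two-sided Wilcoxon signed-rank test to ΔR² = R²(LN) − R²(oracle).

## Surrogates

Both surrogate modes first replace every multi-element response with the
exact linear sum of the neuron's single-element responses (on raw condition
means, `μ'_s = μ_catch + Σ_j (μ_j − μ_catch)`). `noise_only` adds
independent Gaussian noise per partition, matched per neuron × condition to
the empirical across-partition SD of the base data; `signal_plus_noise`
additionally adds one shared Gaussian 31-vector per neuron (SD = the SD
across conditions of the neuron's original tuning) identically to all
partitions. Two estimator details are ours: (1) the across-partition sample
SD at n = 2–3 partitions is debiased by `1/c4(n)` so the surrogate's
*expected sample* SD matches the target (without this the match is ~20%
low); (2) because the supra-linearity bootstrap needs trial-level data, the
per-partition noise draw is realized as per-trial noise with SD
`σ_c·√n_trials-in-partition`, which gives the partition *mean* exactly the
matched SD while keeping within-partition resampling meaningful. A
per-condition vs. pooled noise SD is selectable (`pooled_sd`); per-condition
is the default. Pseudo-sessions for the per-session summary are neuron
groups by index modulo the session count.

## Kinematics

Curvature is computed after resampling the path to 200 uniform arc-length
points, with `numpy.gradient` central differences and one-sided edge
stencils dropped; the default segment is the lower third of the shaft
(nearest the base), configurable as arc-length fractions. Positive κ turns
counterclockwise in image coordinates; |κ| is rigid-motion invariant and
the sign flips under reflection. Accuracy on analytic shapes: 0.5% on a
quarter circle, 2% at a parabola vertex.

## Problem sizes and runtime

Validation studies use sizes where the targeted effects are decidable in
minutes on one CPU: 200 neurons for parameter recovery (weight-recovery
median r ≈ 0.999, median ΔR² ≈ +0.017), 1000 neurons for the
supra-linearity calibration (threshold-LN flag rate ≈ 0.92 at SNR 3,
linear-null rate ≈ 0.04, diagonal enrichment ≈ 0.00 vs ≈ 0.48), 40-neuron
full-trace sessions for end-to-end recovery (per-neuron tuning r ≥ 0.98).
All simulations are seed-deterministic; every pipeline artifact records its
seed and configuration.

## Known limitations

- The min-ratio contamination estimator is biased upward when the somatic
  signal never approaches zero (see above); tuning conclusions are
  invariant, absolute ΔF/F amplitudes are not.
- The catch-ITI baseline inherits slow tails of preceding transients at
  short ITIs (~a few percent at the 2-s default with τ = 1.5 s).
- Percentile bootstrap CIs undercover slightly at n ≤ 20 trials.
- The halves-scheme population display carries the selection leakage
  described above; use thirds when a null-calibrated diagonal matters.
- Surrogate construction assumes Gaussian partition noise; heavy-tailed
  trial distributions would make the SD-matching only approximate.
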