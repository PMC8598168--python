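# combicode

Analysis of **sparse combinatorial population codes** in sensory cortex —
how populations of neurons come to represent *every* combination of a small
set of stimulus elements through stimulus-specific supra-linear summation.

In the motivating experimental design, five whiskers (C2, C1, B1, D1, γ)
are stimulated in all 31 possible combinations plus a no-stimulus catch
condition, while population activity is recorded with two-photon calcium
imaging. `combicode` implements the full analysis chain for such data, plus
a synthetic-session generator with known ground truth so every stage can be
validated end to end:

- **Trace preprocessing** — neuropil correction
  `F_i(t) = R_i(t) − k_i·N_i(t)` with `k_i = min_t R_i(t)/N_i(t)` clamped to
  [0, 1]; ΔF/F against a catch-trial inter-trial-interval baseline or a
  sliding 20th-percentile baseline; nonnegative L1-penalized deconvolution
  into event rates.
- **Trial statistics** — per-trial responses (mean ΔF/F over the 1 s
  stimulus window), running/stationary trial selection, median-rule outlier
  removal (2.3 × IQR), and responsiveness testing (positive mean + Welch
  t-test vs. catch, Benjamini–Hochberg corrected across the 31 stimuli),
  with neurons classed *single*, *multi*, or *combination*.
- **Tuning and supra-linearity** — catch-subtracted tuning curves with
  bootstrap 95% CIs; the **linear difference**
  `LD(s) = r(s) − Σ_{j∈s} r({j})` (supra-linear if > 0); cross-validated
  population matrices (split-half or thirds, reliability gate r > 0.5, rows
  sorted by training-partition preference, held-out partition displayed);
  and a per-neuron bootstrap test for selectively supra-linear summation at
  the top-ranked stimulus.
- **Linear-nonlinear model** — the 7-parameter model
  `r_i = a·f(Σ_j w_j x_ij + h)` with
  `f(x) = (x/2)(1 + erf(x/√2)) + exp(−x²/2)/√(2π)` (a ReLU smoothed by a
  unit Gaussian), fit by L-BFGS-B on squared error, compared on held-out
  tuning curves against a 31-parameter *oracle* that copies the training
  curve verbatim.
- **Surrogate-data controls** — linearized surrogates with
  partition-matched noise (`noise_only`) and with an added reproducible
  stimulus-dependent signal (`signal_plus_noise`), quantified by diagonal
  enrichment of the held-out linear-difference matrix: true deviation from
  linearity is necessary and sufficient for the analysis to report
  supra-linearity.
- **Whisker kinematics** — signed bend curvature
  `κ = (x′y″ − x″y′)/(x′² + y′²)^{3/2}` of tracked whisker paths and the
  free-whisking-subtracted contact-force proxy.

The package is aimed at systems neuroscientists analysing combinatorial
stimulus designs (tactile or visual) and at methodologists interested in
selection-bias-free population analyses.

## Worked example

Narrative scripts live in `examples/`, one per capability. For instance,
`python examples/05_population_code.py` builds a 120-neuron synthetic
population (35% labeled-line, 65% combination-selective), splits trials
into balanced halves, and prints:

```
120 of 120 neurons pass the reliability gate; their preferred stimuli cover 24 of 31 conditions
diagonal enrichment of the held-out LD matrix: +0.481 (0 = no selective supra-linearity)
sorted LD over 119 multi-preferring neurons: rank 1 = +0.662, middle ranks mean = -0.005, last rank = -0.010
-> supra-linearity concentrates at each neuron's top-ranked stimuli and falls off toward the bottom ranks
example neuron bootstrap test: label=supra, LD(top)=+0.887, mean LD(non-top)=+0.222, p_supra=0.0000
```

Read: reliable neurons collectively cover most of the stimulus space; on
held-out data their summation is strongly supra-linear at the stimulus each
prefers (rank 1) and near-linear-to-sub-linear elsewhere — the signature of
a sparse, comprehensive combinatorial code. The surrogate control
(`examples/07_surrogates.py`) shows the same analysis reporting ~nominal
false-positive rates and no diagonal once multi-element responses are
replaced by exact linear sums.

A thin CLI wraps the pipeline for shell use:

```bash
combicode simulate --n-neurons 50 --out session.h5
combicode run --input session.h5 --outdir run1
combicode report run1
```

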