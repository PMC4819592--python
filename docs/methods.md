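# Methods

This note records the scientific and numerical choices behind `boldopt`: what
is modeled, which parameters matter, what the simulations do and do not show,
and where the design was genuinely open.

## The closed loop

One observation is a 10 s stimulus block followed by 10 s baseline at
TR = 2 s. Per-TR scalar signals from the two target regions (occipital,
temporal) are cleaned causally and reduced to a scalar objective by ordinary
least squares against boxcar⊛HRF regressors. Two optimizers consume this
feedback over a discrete stimulus grid:

* **Discrete SPSA** (pure convergence): two probes θ ± cΔ per iteration,
  comparative t-contrast feedback, stopping when the same θ is proposed three
  times in a row, capped at 14 iterations (the 10-minute scan limit).
* **GP Bayesian optimization with EI** (surface mapping): fixed-length
  19-observation runs, the first 5 uniformly random without replacement.

No autocorrelation correction is applied in any GLM or CNR computation; betas
are in raw BOLD units (unit boxcars, unnormalized regressors).

## Signal model and cleaning

* **HRF**: difference of gamma densities with the SPM convention
  (peak 6 s, undershoot 16 s, dispersions 1 s, peak:undershoot 6), sampled at
  the TR and normalized to unit peak. "Canonical" fixes no convention, so the
  most common one is used.
* **EMA detrend**: ema ← α·ema + (1−α)·x with α = 0.96; the detrended sample
  is x − ema. At TR = 2 s this is a first-order high-pass with
  τ = −TR/ln α = 49.0 s and cut-off 1/(2πτ) ≈ 0.003 Hz. The EMA initializes
  at the first sample (no start-up transient toward zero); the first 10 TRs
  are dropped upstream anyway for T1 equilibration. Note a first-order filter
  separates drift (0.0005 Hz) from task (0.05 Hz) by a factor ≈ 6.6 in
  amplitude, not more — the attenuation ratio follows
  |H(f)| = f/√(f² + f_c²).
* **Kalman despike**: scalar random-walk state, measurement variance defaulted
  to the variance of a 20-sample calibration window, process variance 1 % of
  it, spike gate at 3 predicted-SD innovations. A gated sample is replaced by
  the one-step prediction (the spike never enters the state). The published
  filter this emulates is specified only by citation, so this variant is a
  documented approximation; all constants are configurable. Ordering is
  detrend-then-despike.

## Objectives

The two-stimulus comparison fits, per ROI, an intercept plus two regressors on
a 20-TR window laid out as [stim1 5 TR, baseline 5, stim2 5, baseline 5]
(configurable), then computes t = c'β/√(σ̂²c'(X'X)⁻¹c) with c = (0, 1, −1).
Each ROI's t is oriented so positive favors stimulus 1 under the target state
(the temporal t is negated when occipital activity is to be maximized, and
vice versa). When the two ROIs disagree, the t of larger *absolute* value
decides: a large negative t is equally strong evidence for the other stimulus.
The single-stimulus objective is the difference of stimulus betas
(occipital − temporal) from 10-TR windows.

Empirical CNR is mean |objective value| divided by the mean SD of the two ROI
series. The series SD includes task variance, so the estimator is biased low
— in the synthetic fixtures a true amplitude-level CNR of 1.0 reads as ≈ 0.6.

## SPSA parameterization

Defaults: c = 1 grid cell, gain a_k = a/(k+1+A)^0.602 with a = 1.5, A = 1,
cap 14 iterations, convergence after 3 identical consecutive proposals.

The gain follows Spall's scaling guidance: it is matched to the magnitude of
the feedback, not dimensionless. With single-window t-contrasts of |t| ≈ 5–15
for clearly different stimuli, a = 1.5 yields travel steps of 1–3 cells, while
near-optimum comparisons (|t| ≲ 1) round to a zero step and let the estimate
hold — which is what makes three-in-a-row convergence attainable at the true
optimum and rare elsewhere. Much larger gains turn the dynamics bang-bang
(every step clips to a grid edge, and ambiguous probes throw the estimate
across the grid); much smaller gains stall everywhere. Degenerate probe pairs
(both probes clipped onto one corner cell) trigger a bounded redraw of Δ, then
a one-cell nudge toward the grid interior.

## GP model and acquisition

Squared-exponential kernel with per-dimension length scales (ARD), σ² signal
variance, σ_n² white observation noise. The "flat, non-informative mean" is
realized by centering observations on their running mean before conditioning;
predictions add the center back. Factorizations are refreshed after every
observation; jitter escalates 1e−10 → 1e−4 before a failure is raised.

**Hyperparameter tuning** is Type-2 ML: multi-start (8 restarts) L-BFGS-B over
log parameters. Pure ML is exact and is the default. At very low CNR the
marginal likelihood of ~50 observations is multimodal with degenerate global
optima — length scales below the grid spacing (noise interpolation), length
scales spanning the whole grid (a ridge), or signal SD → 0 (the all-noise
explanation). The simulation harness therefore uses a penalized variant
(`prior_strength=0.75`): a log-normal prior on the length scales centered at a
quarter of the grid span (log-SD 0.75), plus a much weaker (log-SD 2) prior on
the two amplitudes centered at sd(y)/√2 that only rules out the exact
degeneracies. The strengths were selected on an independent recovery study
(GP-sampled functions with known σ = 1, l = 3, at noise SD 0.1–2): pure ML
fails recovery for noise ≥ 1, strengths 0.75 and 0.5 recover length scales
within a factor 2 in ≥ 9/10 draws and leave the noise-variance estimate
unbiased; the weaker prior was kept. At low noise the penalty is negligible
and the result coincides with pure ML.

**Expected improvement** defaults to the standard form with s = √var; a
`paper_literal` form substituting the variance for s in both places is
provided for comparison (at these noise levels the two behave similarly). EI
ties are broken uniformly at random from a seeded generator. f_max is the
maximum *observed* value, so under heavy noise it is inflated and EI becomes
exploration-dominated — intended behavior for surface mapping.

## The synthetic subject and ground truth

* **Study-2 ground truth** (19×19): a positive squared-exponential bump at the
  grid center minus one at each corner, widths 4 grid cells, rescaled exactly
  so mean |value| = 0.606 — the amplitude that places the Gaussian-noise SD at
  6.06 for CNR 0.1 and 0.337 for CNR 1.8. The functional form is a stand-in:
  only the qualitative shape (center maximum, corner minima, smooth
  transitions) is constrained, and the surface's smoothness sets the
  information ceiling of any fixed observation budget. In the CNR study noise
  is injected at the amplitude level (value + N(0, SD)) at every stage,
  including hyperparameter tuning and burn-in; full BOLD-level synthesis is a
  separate path used for end-to-end integration tests.
* **Study-1 subject** (SPSA): occipital amplitude follows a saturating sigmoid
  of visual complexity level, temporal amplitude the same sigmoid of auditory
  level — 0.5(1 + tanh((level − 5.5)/2.5)) — with white noise SD 0.08 on the
  20-TR windows. Saturation at the extremes (two rich movies differ little;
  two near-silent sounds differ little) is deliberate and matters: it makes
  comparisons adjacent to the optimum statistically quiet, so the convergence
  rule can trigger there, while mid-grid comparisons produce decisive t values
  (≈ 5–15), typical of strong sensory block designs. With these conditions the
  optimizer converges at the planted optimum in ≈ 80 % of runs with median 8
  iterations and essentially never under information-free feedback (≈ 4 % at
  coin-flip scores of decisive magnitude).

What the generators do **not** emulate: physiological (cardiac/respiratory)
noise, motion, temporally autocorrelated noise, habituation across runs, and
inter-subject variability. Passing tests therefore show the machinery is
correct and well-calibrated under idealized noise, not that real scanner data
would behave as cleanly.

## Permutation tests

Both tests are one-tailed (smaller is better) and use the add-one estimator
p = (1 + #{null ≤ observed})/(1 + N), which cannot return zero; the estimator
choice is ours.

* **Convergence test**: the null replays the SPSA update dynamics (vectorized
  over all permutations and runs) with the pooled empirical objective values
  randomly reassigned to iteration slots; each pooled value is used once per
  cycle through the pool, and runs are capped at 50 iterations. The observed
  statistic treats non-converged or faulty runs as 50 (conservative) or as the
  null mean (liberal). Because real scans stop at 14 iterations while null
  replays run to 50, the test as deployed on scan-length runs is conservative;
  exchangeability (uniform p under the null) holds exactly when observed runs
  are simulated to the same cap, which is how calibration is verified.
* **Group-optimum test**: values are shuffled against coordinates and the GP
  refit; since the coordinates (hence the kernel matrix) are fixed, one
  Cholesky factorization serves all permutations, and the full null
  distribution of optimum distances is computed in a single vectorized solve.

## Problem sizes

The test suite exercises the CNR study at 100 simulations × 50 iterations per
CNR level over {0.1, 0.3, 0.8, 1.8} (the package's standard verification
sweep; the full-length 100-iteration traces change nothing before iteration
50). Permutation-test calibration uses 40–100 replicates at 99–200
permutations with 6-run batches; power checks use 14 runs at 1,000
permutations. The acceptance script runs the CNR 0.3 condition at 100
simulations × 50 iterations, tuning on 50 observations.

## Known limitations

* The center-peak/corner-minima ground-truth surface is one member of an
  unidentified family;
  reported simulation accuracies (e.g., spatial correlation ≈ 0.62–0.68 at CNR
  0.3 after 50 observations, against an ideal-hyperparameter ceiling of
  ≈ 0.69 under this surface) shift with its smoothness.
* Hyperparameter tuning from 50 noisy observations is intrinsically
  high-variance at CNR ≤ 0.3; the weak hyperpriors remove degenerate modes but
  not the sampling variability of the single tuning draw.
* The Kalman stage approximates a filter specified only by citation.
* The SPSA gain schedule is calibrated to t-scale feedback; feeding it
  objectives on other scales requires rescaling `step_gain_a`.
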