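# Methods

`robint` models two-alternative perceptual decisions (random-dot motion
discrimination) made by *robust* neural integrators — accumulators that
ignore momentary net drive below a preset limit. The package quantifies the
tradeoff that limit embodies: robustness against mistuned recurrent feedback
versus sensitivity to weak evidence.

## Model

### Sensory stage (`sensory_synth`)

Two pools of 100 direction-selective neurons fire at rates linear in motion
coherence `C` (percent):

    mu_pref(C) = r0 + 0.4 C,    mu_anti(C) = r0 - 0.2 C,    r0 = 20 sp/s,

clipped at zero. Spiking is modeled as correlated, unbiased random walks to
a unit threshold with reflection at zero (reset after a spike). Two
empirical calibrations pin the model to its targets:

* **step SD** — bisection against the simulated rate until the pool matches
  the rate law within 2% (the analytic seed `sd ~ sqrt(rate * dt)` comes
  from the reflected-Brownian first-passage time);
* **common-input weight** — each increment is
  `sqrt(w) * shared + sqrt(1 - w) * private`; because the spiking
  nonlinearity attenuates correlation, `w` is bisected until the pairwise
  spike-count correlation in 100-ms windows matches the target 0.11
  (calibrated `w ~ 0.17`). Setting the weight to the target correlation
  itself, the naive choice, yields count correlations near 0.07.

Each spike is convolved with a unit-jump exponential kernel (tau_syn =
20 ms); summed pool output is normalized by `n_neurons * tau_syn` so its
mean equals the per-neuron rate in sp/s. The normalized pooled output is
then replaced by an Ornstein–Uhlenbeck (OU) surrogate whose mean follows the
rate law exactly and whose stationary variance and correlation time are fit
from a 500-s simulation per rate (log-linear fit to the normalized
autocovariance above 0.05). The fitted table — variance ≈ 1.86 × rate,
tau ≈ 20.5 ms — ships as `data/ou_fits_default.json`, keyed by pool rate
and linearly interpolated; regenerate it with
`analysis/01_calibrate_sensory.py`.

Additive zero-mean OU noise (variance `nu_gamma / 2` per pool, tau 20 ms)
represents direction-unselective input. The integrator inputs are the
differenced streams

    dI_l = (I_l + eta_l) - (I_r + eta_r),    dI_r = -dI_l,

and the robustness limit is normalized by the stationary SD
`S = sqrt(v_l + v_r + nu_gamma)`. Since all four components are independent
OU processes with a common correlation time, `dI` is itself OU with the
means differenced and variances summed; the Monte-Carlo engine exploits this
exact reduction.

**Choice of `nu_gamma` (default 630).** The additive-noise variance is the
model's free sensitivity parameter, fit to behavior in the source study
(whose fitted values are not available). We calibrate it once, in closed
form, so that the perfectly tuned integrator reaches 85% correct at
C = 12.8 after 500 ms of viewing — the operating point typical of primate
psychophysics on this task. The resulting momentary SNR of the differenced
stream is s = m/S ≈ 0.289, which independently reproduces the study's
reported equivalent sampling interval (~37 ms; we obtain 35–38 ms, ≈ twice
the 20-ms correlation time, as the diffusion limit predicts). The value is
fixed ahead of all simulation experiments and not tuned afterwards.

### Integrator stage (`integrator_core`)

Firing rates E_l, E_r of two accumulators obey, per Euler–Maruyama step,

    tau_E dE/dt = 0                          if |beta E + kappa dI| <= kappa S R-hat
                  beta E + kappa dI          otherwise,

with kappa = 1/9, tau_E = 20 ms, E(0) = 0, and reflecting floors at zero.
The mistuning `beta` (imbalance of recurrent excitation versus leak) is
constant within a trial and Gaussian across trials, N(beta_bar,
sigma_beta^2). Following the source's computational recipe, mistuned
conditions sweep a grid of >= 19 equally spaced beta values spanning
+/- 3 SD and average outcomes under the Gaussian weights
("figure-reproduction mode"); per-trial sampling from the same grid is also
available. Order of operations in a step: dead-zone test on the full drive,
then the update, then the floor clamp — so the floor can never un-freeze a
frozen state.

Tasks: *race* (first accumulator at theta wins; RT = decision time +
350 ms nondecision time; trials that never cross within a 10-s cap are
logged, assigned a fair-coin choice, and censored at the cap), *compare*
(argmax at experimenter-set time T, exact ties split by a fair coin), and
*bounded* (an accumulator reaching theta is absorbed there; the first to
absorb determines the report).

Model corners: baseline (sigma_beta = 0, R-hat = 0), mistuned (0.1, 0),
robust (0, 1.25), recovery (0.1, 1.25).

### Analytical frameworks

`seq_analysis` treats evidence as i.i.d. Gaussian increments
Z ~ N(mu, sigma^2) whose mass inside (-R, R) collapses to an atom at zero.
Closed-form Gaussian partial moments give the rectified mean/variance and
the MGF; the nontrivial root of M(omega) = 1 is found by bracketed search
and equals -2 mu / sigma^2 for every dead-zone width (the exponential
symmetry f(z) = f(-z) e^{-h0 z} survives symmetric rectification). Hence in
the race task accuracy `1/(1 + e^{theta h0})` is invariant in R-hat while
mean decision time `(theta / E[Z_R]) tanh(-theta h0 / 2)` grows only as the
rectified mean shrinks — and that shrinkage is cubic,

    E[Z] - E[Z_R] = mu sqrt(2/(9 pi)) e^{-s^2/2} R-hat^3 + O(R-hat^5).

The Wald formulas assume negligible threshold overshoot; oracles in the
test suite use increment SDs <= theta/50 so the overshoot bias stays below
the Monte-Carlo tolerance.

`corr_theory` handles the temporally correlated stream: for
E(t) = int Z dt', `Var[E(t)] = 2 int_0^t (t - tau) A(tau) dtau` with A the
autocovariance; for the OU input this integrates to
`2 v tau [t - tau (1 - e^{-t/tau})]`. Dead-zoning the stream (symmetric,
|z| < R-hat * SD -> 0, matching the increment-distribution definition; a
one-sided variant is available behind a flag for sensitivity analysis)
shortens the correlation time of the surviving signal, so the integrated
SNR — and the erf accuracy it implies — degrades far more slowly with
R-hat than in the matched independent-sample model. The rectified mean is
exact (partial moments); the rectified autocovariance is estimated from an
exactly simulated OU path by the biased (divide-by-n) FFT estimator after
mean subtraction, which keeps the estimate positive semidefinite.

## Numerical choices

* OU paths use the distribution-exact update
  `x' = mu + (x - mu) e^{-dt/tau} + sqrt(v(1 - e^{-2 dt/tau})) xi`, with
  stationary initial draws.
* Default integration step dt = 0.1 ms for pure-theory estimates; the
  simulation experiments use dt = 0.5 ms after checking one condition for
  insensitivity (accuracies move < 1 SE between 0.1 and 0.5 ms).
* Autocovariance estimates default to 2^22 samples; tolerance scales as
  1/sqrt(n). Integrated-moment quadrature is trapezoidal with a tail
  cutoff once |A| < 1e-6 A(0) (a warning fires if truncation happens while
  the tail is above 1% of A(0)).
* Threshold optimization is a coarse-to-fine grid search resolving theta to
  0.1 (0.5 in the scaled-down sweeps); boundary maxima trigger a warning.
  Behavioral fitting is a joint grid search over (theta, nu_gamma)
  minimizing summed squared error with accuracy as a fraction and RT in
  seconds, so both terms are O(1).
* Matched-RT comparisons between models interpolate accuracy piecewise-
  linearly in mean RT between threshold-grid points.
* Seeding: one master seed per run, split with `numpy` `SeedSequence`
  spawning, so trials, conditions and noise sources are independent and
  reproducible.

## Problem sizes

Figure-level experiments and the acceptance script run at desk scale: 2000
trials per beta-grid point (1500 in the race sweeps), 19-point beta grid,
dt = 0.5 ms, 2^22-sample autocovariances — about a minute end-to-end for
the headline numbers. The original-scale settings (>= 10^4 trials,
dt = 0.1 ms, 2^27 samples) are supported by the same entry points via their
`n_trials` / `dt` / `n_samples` arguments; Monte-Carlo standard errors are
reported everywhere, and experiment manifests flag any run below the
original scale.

## What the synthetic data does and does not emulate

The generator reproduces the statistics the theory needs: rate–coherence
linearity, weak pairwise spike-count correlation (0.11), synaptic
smoothing, and the stationary mean/variance/correlation-time of pooled
evidence. It does not attempt Poisson spike-train realism, Fano-factor
structure beyond the random-walk model, rate adaptation, or non-stationary
stimuli. Passing tests therefore certify the decision-theoretic claims
under stationary OU-like evidence, not fidelity to any particular
electrophysiological dataset. Behavioral fitting is exercised against
synthetic tables generated by the model itself (plus noise); fitting real
psychophysics would additionally confront model misspecification.

## Known limitations

* At a vanishing race threshold, accuracy tends to Phi(s) — the sign of
  the initial stationary evidence sample — not 0.5; the familiar chance
  limit holds only for white-noise (uncorrelated) input.
* The reflecting floors make the race a drawdown race: accuracy is
  slightly below the two-sided Wald prediction at matched threshold. The
  sequential theory is recovered exactly when the floor is removed (see
  the cross-module test).
* The fixed-N CLT accuracy degrades once the atom at zero dominates
  (p0^N approaching 1/2, e.g. R-hat = 2 with N = 14): it overestimates the
  tie-weighted accuracy by a few percentage points there.
* At matched mean RT the perfectly tuned robust integrator (R-hat = 1.25)
  shows a real but small accuracy deficit (~1 percentage point at 10^4
  trials) rather than exact coincidence with the baseline — small compared
  with the ~10-point mistuning cost it protects against.
* Reaction-time *distributions* (shapes, tails, collapsing bounds) are out
  of scope; only means are modeled.
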