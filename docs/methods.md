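# Methods

## Model and inference

The generative model is a scalar latent state driven by observed commands
through unknown linear weights, with Gaussian process and sensor noise
(README, "The problem"). Because the model is linear-Gaussian and the
weights are static, the exact joint posterior over `(z_n, w)` given all
commands and measurements is Gaussian; the PIAF recursion in `piaf.core`
propagates its five sufficient statistics `(μ_z, μ_w, Σ_zz, Σ_ww, Σ_zw)`
exactly. It is algebraically identical to a Kalman filter on the augmented
state `(z, w)` with transition `[[1, q̇ᵀ], [0, I]]`, process covariance
`diag(σ_p², 0, …)`, observation row `[1, 0, …]` and noise `σ_s²`; the test
suite asserts this equivalence against `baselines.joint_kalman_step` (an
independent textbook implementation) and against brute-force Gaussian
conditioning, at 1e-9 relative over randomized beliefs and `D_q ∈ {1,2,3}`.

Consequences worth keeping in mind when reading results:

* **Optimality.** No alternative estimator of `w` within this model class
  can beat PIAF's mean squared error; comparisons measure how much the
  baselines lose, never the reverse.
* **Pathwise calibration.** For an exact Bayes filter,
  `E[(μ_z − z)² | data] = Σ_zz` holds on every path, so the Monte-Carlo
  ratio (observed MSE)/(mean reported variance) converges to 1 at every
  iteration. Deviations we measure (≈1.1–1.4 at early iterations, ≈1.0
  late) are Monte-Carlo noise, not miscalibration. A substantial, persistent
  late-time over- or under-estimation would indicate a bug, and the
  acceptance test treats it as such.

## Baselines and couplings

* **Known-weight Kalman filter** (`kalman_step`): prediction `μ_z += q̇ᵀw`,
  `Σ_zz += σ_p²`; the standard scalar update. Defines the performance floor;
  its long-run state MSE is limited by `σ_p`.
* **Classical RLS** (`classical_rls_step`): information-form least squares
  on pairs `(q̇_n, ẋ_n = x_n − x_{n-1})`, with a `1e-8` ridge on the
  information matrix for the pre-identifiability phase and the ordinary
  least-squares standard-error covariance
  `σ̂_w² = s² (Σ q̇q̇ᵀ)⁻¹, s² = rss/(n − D_q)`. While the residual degrees
  of freedom are non-positive, the variance is reported as a large sentinel
  (1e12) rather than a crash or a false zero.
* **Modified-recursion RLS** (`rls_modified_piaf_step`): the joint update
  with the incoming cross-covariance zeroed at prediction and the sensor
  variance inflated to `2σ_s²` — the assumption that differenced
  observations are independent, written as a filter.
* **RLS→Kalman** (`run_rls_to_kalman`): per step, the Kalman side predicts
  with the learner's current `μ_w`, inflating its prediction variance by
  `q̇ᵀσ̂_w²q̇` (no cross-covariance is tracked), updates on `x_n`, and only
  then does RLS consume the differenced raw pair — so the prediction never
  uses information from the measurement it predicts. Differencing needs two
  samples: the learner is silent at step 1 and the Kalman side starts from
  the learner's prior (`μ_w = 0`, `σ_w² = 1`).
* **Kalman↔RLS** (`run_kalman_rls_loop`): identical wiring except RLS
  consumes differences of consecutive Kalman *posterior means*. The loop is
  closed: the filter's own predictions leak into the learner's data, the
  learner's residual variance `s²` collapses, the injected `q̇ᵀσ̂_w²q̇`
  vanishes, the Kalman gain settles at its small steady-state value, and
  the weight estimate freezes — the self-delusional loop. The RLS side
  deliberately keeps its i.i.d. assumption and its own residual-based `s²`;
  that blindness to filtering-induced correlation is the failure being
  demonstrated.

## Synthetic data

`piaf.generative` simulates the two study regimes: sinusoidal commands
`q̇_n = ω cos(ωn + φ)` with period `T = 50` (`ω = 2π/T`), and i.i.d.
Gaussian commands `N(0, ω²/2)` with matching power. Defaults throughout:
true `w = 1`, `σ_s = 2` (a *standard deviation*; the state channel then runs
at a 1:8 noise:signal MSE ratio against the unit-amplitude signal), `σ_p`
per experiment, start phase `φ ~ U[0, 2π)` drawn per replicate with
`z_0 = sin(φ)`, and priors `μ_z = 0`, `Σ_zz = 10⁴` (range of the unknown
signal), `μ_w = 0`, `Σ_ww = I`, `Σ_zw = 0`. One master seed per experiment;
replicate `k` uses the `k`-th spawned substream, so any single run is
reproducible in isolation.

What the generator does *not* emulate: nonlinear or time-varying forward
models, non-Gaussian noise, multidimensional latent states, and any
sensorimotor delay. Passing tests show the estimators behave as the theory
predicts *within* this model class; they say nothing about robustness to
model mismatch.

## Monte-Carlo engine and problem sizes

Replicate studies run through `piaf._engine`, which vectorizes the scalar
(`D_q = 1`) recursions across replicates (one numpy operation per statistic
per step). The kernels are an optimization only: tests compare them
step-for-step against the per-step reference implementations at 1e-9.
Standard problem sizes, chosen to keep every study desk-scale (seconds to
tens of seconds on one CPU): 300 replicates × 10⁴ steps for
weight-learning comparisons, 1000 × 10⁴ for calibration curves,
100 × 10³ for the no-process-noise tracking demonstration, and
50 × 10⁵ for the long-horizon loop-stagnation study.

## Metrics

* `first_crossing`: first iteration at which a replicate-averaged curve
  reaches a threshold, refined by log-log interpolation (the curves are read
  on double-logarithmic axes); `speedup_factor` is the ratio of two
  crossings. Curves that never cross report NaN, never a fabricated value.
* `variance_calibration`: per-iteration MSE/reported-variance ratios for
  both channels.
* `plateau_mse`: geometric mean over the trailing fraction (default 20%) of
  iterations — geometric, because plateau levels spread over decades.
* `detect_stagnation`: a step is stagnant when the log-log slope of the
  error curve over a trailing window is above `−ε` *and* the curve sits
  above `factor ×` an achievable floor; a run is flagged when it ends in a
  stagnant stretch at least one window long. The defaults
  (`ε = 1e-3`/decade, `factor = 10`) treat only a near-exactly-flat curve as
  stagnant; on real closed-loop runs the frozen weight estimate still drifts
  at ≈5e-2/decade, so the operational setting used in the long-horizon
  diagnosis is `ε = 0.2`/decade with a window of 5000 at the 10⁵-step
  horizon — "decaying at least five times slower than the optimal 1/n
  rate", a definition fixed by that decay-rate argument. Both knobs are
  exposed because stagnation has no single canonical definition.

## Numerical choices

`Σ_ww` is re-symmetrized after each rank-one downdate (exactly symmetric in
real arithmetic, drifts in floating point). No covariance flooring or
jitter is applied by default; a nonnegative `jitter` config field exists for
long-horizon robustness experiments. The prediction step's cross term
`2 Σ_zw q̇` can be negative, so the prior state variance occasionally grows
by less than `σ_p²`; such steps are counted and logged
(`FilterRun.n_variance_drops`), not forbidden — positive semidefiniteness of
the joint covariance is the invariant that is enforced and tested. In the
degenerate fully-noiseless case (`σ_s = 0` with an exact prediction) the
innovation variance is zero and the update is skipped as vacuous; the
per-step API raises instead, since reaching that state silently usually
indicates a configuration error.

## What reproduces and what does not

The acceptance suite measures the study's headline numbers honestly, and
three of them come out differently from their published-style values. These
are properties of the problem, not implementation defects; the oracle
equivalences above pin the implementation down to the mathematics.

* **Weight-learning speedup over RLS→Kalman under sinusoidal control
  (measured ≈ 1 at threshold 1e-3, not ≥ 10).** Under smooth periodic
  control, least squares on differenced raw measurements enjoys
  sensor-noise cancellation: the shared noise term of consecutive
  differences enters with opposite signs, and summation by parts leaves an
  effective error variance ≈ `2σ_s²/N` — the same asymptotic rate as the
  Bayes-optimal filter, whose own information bound (marginalizing the
  unknown `z_0`) is also `2σ_s²/N`. Crossing 1e-3 happens deep in this
  asymptotic regime, so the ratio is forced toward 1 for *any* correct
  OLS-based learner. Large (10–100×) horizontal offsets do arise in this
  comparison, but only (a) against the independence-assuming
  modified-recursion RLS, which cannot exploit the correlation (the package
  includes it as method `"rls"`; at loose thresholds it needs 10–30× more
  samples, and under random control it never catches up), or (b) under
  random control, where the command-driven signal accumulates and the
  optimal filter gains a qualitatively faster rate.
* **Trailing-window tracking RMS (measured ≈ 0.11, not < 0.1).** With
  `σ_p = 0` the state MSE decays like `2·(2σ_s²)/n` (the two-fold
  learning overhead); averaging it over iterations 301..1000 front-loads
  the not-yet-converged steps and integrates to ≈ 0.11. The *per-step* RMS
  deviation does fall below 0.1 from roughly iteration 800 on.
* **Closed-loop plateau ratio (measured ≈ 60–95×, not ≈ 10×).** The
  qualitative phenomenon is robust — every run stagnates, endpoints spread
  over more than a decade, the plateau sits far above the `σ_p` floor — but
  the *level* depends on how early the loop's confidence collapses, which in
  turn depends on the exact standard-error recursion injected into the
  Kalman prediction. With the ordinary OLS standard error used here, the
  gain collapses within a few hundred steps and the weights freeze largely
  unlearned; gentler variance wirings stagnate later and lower. The plateau
  level should be read as order-of-magnitude.

## Limitations

Scalar latent state only (weights may be vector-valued, and all per-step
code paths accept `D_q > 1`, but the vectorized Monte-Carlo engine and the
preset catalog are scalar-command). No smoothing, no control selection, no
forgetting-factor RLS, no nonlinear (EKF/UKF) extensions.
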