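# Methods

## The estimation problem

A biochemical reaction network with `D` species and `r` reactions defines a
continuous-time, discrete-state Markov jump process: each reaction `j` fires
at a state-dependent hazard (propensity) `v_j(x, theta)` and changes the
molecule-count vector `x` by the j-th column of the stoichiometric matrix
`S`.  Given a time series `nu_0, ..., nu_n` of molecule counts observed at
times `t_0 < ... < t_n`, the likelihood of the kinetic parameters `theta`
factorises, by the Markov property, into a product of transition
probabilities `p(nu_i | nu_{i-1}, dt_i, theta)` with `dt_i = t_i - t_{i-1}`.
These transition probabilities solve the chemical master equation (CME) and
are intractable for all but the simplest networks.

`mssfit` replaces each transition probability with a Gaussian surrogate,
computed independently on each inter-observation interval:

* **mean** `x(dt_i; theta, nu_{i-1})`: the deterministic rate-equation
  solution `dx/dt = S v(x, theta)` restarted at the previous *datum*
  (the multiple-shooting step — no global trajectory is ever fitted);
* **covariance** `Sigma(dt_i; theta)`: the solution of the linear noise
  approximation (LNA) covariance equation

      dSigma/dt = J Sigma + Sigma J^T + D / Omega,     Sigma(0) = 0,

  with drift Jacobian `J(x, theta) = S dv/dx` and diffusion matrix
  `D_ij = sum_k S_ik S_jk v_k`, both evaluated along the evolving mean
  `x(t)` within the interval.  `Omega` is the system volume; all built-in
  benchmarks work in molecule counts with `Omega = 1`.

The negative log-likelihood is then

    F(nu, theta) = - sum_i log N(nu_i; x(dt_i; theta, nu_{i-1}), Sigma(dt_i; theta)),

a completely deterministic, smooth function of `theta`, so estimation is
ordinary gradient-based minimisation — no stochastic simulation and no CME
solution enters the objective.  The evaluation cost per interval is one
integration of `D + D(D+1)/2` coupled ODEs.

Because each interval is re-initialised at the observed datum, the Gaussian
assumption only has to hold *locally*, over one inter-sample distance, not
over the whole horizon.  This is what lets the method survive regimes where
a global Gaussian (or deterministic least-squares) description fails:
die-out, near-extinction, and strongly fluctuating trajectories.

Statistically the model is a Gaussian nonlinear first-order autoregression;
the estimator is the exact MLE of that surrogate model.

### Partial observation

When only a subset of species is measured (observation model
`obs_idx`), the density above is evaluated on the observed marginal —
`x^obs` and the `Sigma^obs` block — and the unobserved components of the
re-initialisation state are propagated deterministically: the hidden part of
interval `i`'s initial state is the hidden part of interval `i-1`'s mean
solution, seeded at `t_0` by a hidden initial value that is either known or
added to the optimisation vector (bounded below by zero).  This is the
simplest possible state estimate — deliberately so; no smoothing and no
LNA cross-covariance conditioning is used, keeping the intervals
independent.  The fully observed case is the special case with no hidden
components, and the code reduces to it exactly.

### Measurement noise

Additive Gaussian measurement noise with covariance `Sigma_meas` (assumed
zero-mean, inter-temporally independent) enters in two places: the
per-interval covariance becomes `Sigma^obs + Sigma_meas`, and the noisy
datum itself still serves as the re-initialisation state (again the simplest
usable state estimate).  With `noise_std_estimable` the scalar noise s.d.
`sigma` (so `Sigma_meas = sigma^2 I`) is estimated jointly with `theta` on
the log scale.

### Predecessor objective

For old-vs-new comparisons, `constant_variance_objective` replaces
`Sigma(dt_i)` by `c * I`.  Up to an additive constant this is half the
multiple-shooting least-squares residual sum divided by `c`, so its
minimiser is `c`-independent (`c = 1` by default; inside the optimiser the
additive constant is dropped, which keeps the relative stopping rule
`c`-invariant too).  On designs where only few reactions fire per interval
this objective leaves a nearly flat valley in the absolute rates — the
failure mode that motivates the LNA weighting.

## Residual diagnostic

Inverting the surrogate: if the Gaussian approximation holds at the true
parameters, the standardised one-step residuals

    r_i = (Sigma_i^obs + Sigma_meas)^{-1/2} (x(dt_i) - nu_i),   i = 1..n,

are i.i.d. standard normal in every component.  `approximation_residuals`
computes them with the *symmetric* (eigendecomposition) matrix square root —
any fixed root convention yields N(0, I) under the null, and the symmetric
root is permutation-covariant; the sign convention (prediction minus datum)
is immaterial under the symmetric null.  `normality_check` applies a
one-sample Kolmogorov–Smirnov test against N(0, 1) per component (default
level 0.01).  The check is conservative as a rejection device: the
covariance acts only as a weighting factor, so estimation often succeeds
where the test fails (die-out and explosion trajectories are typical
examples); reporting language in the CLI reflects that.

## Exact immigration-death oracle

The immigration-death process (influx at rate `theta1`, per-capita decay at
rate `theta2`) has an analytic transition law: survivors of the initial
`n0` molecules are `Binomial(n0, e^{-theta2 dt})` and immigrants are
`Poisson(theta1/theta2 (1 - e^{-theta2 dt}))`, independently; the
transition pmf is their convolution.  This supplies

* a correctness anchor: for linear propensities the LNA moment equations
  coincide with the exact CME moment equations, so the integrated mean and
  variance must match the pmf moments to integrator tolerance (asserted at
  1e-8 in the tests and acceptance suite);
* an exact maximum-likelihood estimator (`exact_id_mle`) against which the
  Gaussian surrogate's statistical efficiency is measured.

## Numerics

* **Integrators.**  The public single-interval API uses `scipy`'s LSODA with
  `rtol = 1e-8`, `atol = 1e-10` (stiff-capable reference).  The likelihood
  machinery uses a fixed-step classical Runge–Kutta scheme, 24 steps per
  interval by default, with two equivalent implementations: a vectorised
  numpy path and a numba-compiled kernel (bitwise-identical, cross-checked
  in tests; the numpy path is the automatic fallback).  Fully observed
  intervals are mutually independent given the re-initialisation and are
  integrated in a single batched pass; hidden-state chains are integrated
  sequentially in one compiled sweep.  On the benchmark models the
  fixed-step scheme agrees with the reference to better than 1e-6
  (absolute, on means and covariances); being fixed-step it is also exactly
  smooth in `theta`, which keeps finite-difference gradients clean.
* **Covariance regularisation.**  Each transition covariance is symmetrised;
  if its smallest eigenvalue falls below `eps = 1e-8 * max(1, trace/D)`,
  `eps * I` is added.  Near-singular covariances arise legitimately (states
  at zero after die-out); the jitter keeps the density evaluable without
  materially changing well-conditioned intervals.  Densities are evaluated
  by Cholesky factorisation.
* **Optimisation.**  Bounded quasi-Newton (L-BFGS-B) on `log theta`
  (positivity by construction), numerical gradients, default box
  `[1e-6, 100]` per parameter, gradient tolerance 1e-6 and relative
  objective tolerance 1e-12.  A fit counts as converged only if the
  optimiser succeeds *and* the estimate lies strictly inside the box
  (relative margin 1e-6): boundary solutions are reported as
  non-converging, mirroring the study convention.  Hidden initial states
  are optimised on the linear scale with a non-negativity bound; the noise
  s.d. on the log scale.  Multi-start is available (seeded multiplicative
  perturbations of the start, factor U[0.5, 2] per component) but the
  benchmarks use a single start.
* **Sampler.**  `approximate_simulate` draws each next state from the
  Gaussian transition law conditioned on the previously drawn state, rounds
  to the nearest integer and clamps at zero (rounding is part of the
  construction; negativity handling is a package choice, as a Gaussian tail
  can cross zero).  `round_states=False` gives the un-rounded chain used to
  calibrate the residual diagnostic.

## Simulation-study harness

Ground-truth data are generated with the exact Gillespie direct method
(exponential waiting times, reaction chosen proportionally to propensity),
sampled right-continuously on the measurement grid: the value recorded at a
grid time is the state immediately current there.  An event ceiling
(default 1e7) aborts runaway trajectories with a distinguishable
explosion status carrying the partial series.

A `Scenario` fixes model, true parameters `theta0`, grid (`n_points`,
`dt`), initial state (explicitly, or `"steady_state"` = `theta1/theta2`
for the immigration-death model), observation scheme, noise level,
replicate count and estimator variant.  `run_study` simulates
`n_replicates` independent series (replicate `i` uses seed
`base_seed + i`, so any replicate can be re-run in isolation; noise and
start-perturbation seeds live in disjoint offset streams), estimates each,
and reports

* `av`: mean of the converged estimates,
* `ARE`: mean of `|theta_hat - theta0| / theta0` (componentwise),
* `medRE`: median relative error,
* `div`: count of non-converging replicates (excluded from the statistics,
  reported separately).

Estimation starts at `theta0` perturbed multiplicatively by seeded
U[0.5, 2] draws per component — replicate-level statistics, not individual
optimiser paths, are the reproducible quantity.

**Ranking external estimates.**  A single published estimate from another
method is ranked among the replicate estimates by scalar relative error,
taken as the *mean of the componentwise relative errors* (the same
structure as ARE); ties favour the external estimate.  The scalarisation is
a package convention — there is no canonical way to sort multi-parameter
errors — and is stated here prominently for that reason.

**Trajectory trichotomy.**  Predator–prey realisations are classified
post-hoc: "die-out" if every species hits zero before the horizon,
"explode" if the event ceiling was hit or any count exceeds 1e4 (both
thresholds configurable), "normal" otherwise; a scenario can request
replicates of one class, scanning the seed stream until enough are found.

## Built-in benchmark models

* **Immigration-death** (1 species, 2 reactions, `S = (1, -1)`),
  `v = (theta1, theta2 x)`; stationary law Poisson(`theta1/theta2`).
* **Auto-regulatory gene network** (8 reactions): a promoter `DNA` is
  reversibly repressed by a protein dimer `P2` (`DNA + P2 <-> DNA.P2`),
  transcribes `mRNA`, which is translated to protein `P`; `P` dimerises
  reversibly to `P2`; `mRNA` and `P` degrade.  The total promoter copy
  number `DNA_t = DNA + DNA.P2` is conserved, so the network is represented
  on the 4 independent species (DNA, P2, mRNA, P) with
  `DNA.P2 = DNA_t - DNA` folded into the unbinding propensity — in the full
  5-species space the conservation makes every covariance singular.  The
  dimerisation hazard is `theta5 * P^2` (plain mass action, consistent with
  the model's rate-equation form across SSA, mean and LNA); the
  combinatorial convention `theta5 * P(P-1)/2` is available per reaction
  but off by default.  Benchmark truth
  `theta0 = (0.1, 0.7, 0.35, 0.3, 0.1, 0.9, 0.2, 0.1)`, initial counts
  P2 = 6, mRNA = 8, P = 25, and DNA = 6 (`DNA_t = 10`) or DNA = 2
  (`DNA_t = 2`).
* **Lotka–Volterra** (2 species, 3 reactions): prey birth `theta1 y1`,
  predation `theta2 y1 y2`, predator death `theta3 y2`;
  `S = [[1, -1, 0], [0, 1, -1]]`; benchmark truth `(0.5, 0.0025, 0.3)`
  from `(y1, y2) = (71, 79)`.

Rate laws are restricted to products of polynomial factors in single
species counts (plain powers, combinatorial factors, conserved-moiety
complements), which covers mass action exactly; arbitrary kinetics would
require a user-supplied rate/Jacobian pair and is out of scope.

## What the synthetic data do and do not emulate

The generator produces *exact* realisations of the assumed jump process,
observed on a regular grid, optionally with i.i.d. Gaussian measurement
noise.  Real single-cell or biochemical data additionally feature model
misspecification, extrinsic (cell-to-cell) variability, non-Gaussian and
state-dependent measurement error, and irregular sampling (irregular grids
are supported, but the benchmarks are equidistant).  Passing the replicated
benchmarks therefore demonstrates that the estimator recovers parameters of
the *assumed* process from realistic amounts of data — not robustness to
misspecification.

## Problem sizes and reproducibility

The replicated benchmarks run 100 replicates per scenario, as in the study
design they reproduce; the dense-sampling gene-network check runs 10
replicates (full scale is a configuration change:
`n_replicates=100`).  Every random quantity — trajectories, noise, start
perturbations — derives from the scenario's `base_seed`, so studies are
bitwise reproducible.

## Known limitations

* The Gaussian surrogate degrades when inter-sample distances are long
  enough for strongly non-Gaussian transition laws (multimodality,
  absorption atoms); the residual check flags, but does not repair, this.
* Hidden-state propagation ignores observed-hidden correlations; with many
  hidden species or long horizons the propagated chain can drift.
* The box-constrained local optimiser finds local minima; flat ridges
  (e.g. the constant-variance objective on sparse designs) can stall it —
  reported via the convergence flag, and multi-start is available.
* No confidence intervals or posterior uncertainty; replicate spread is the
  only uncertainty measure provided.
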