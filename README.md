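# mssfit

Deterministic maximum-likelihood parameter estimation for **stochastic
reaction networks** observed as discrete time series of molecule counts —
for systems biologists who need to fit kinetic rate constants of a Markov
jump process without running stochastic simulations or solving a chemical
master equation inside the objective function.

## The method

For data `nu_0, ..., nu_n` at times `t_0 < ... < t_n`, the likelihood of the
rate constants `theta` factorises into transition probabilities
`p(nu_i | nu_{i-1}, dt_i, theta)`.  `mssfit` approximates each factor by a
Gaussian computed on its own interval, restarted at the previous datum
(a multiple-shooting scheme):

* mean = the rate-equation solution `x(dt_i; theta, nu_{i-1})` of
  `dx/dt = S v(x, theta)`,
* covariance = the linear-noise-approximation solution of
  `dSigma/dt = J Sigma + Sigma J^T + D/Omega`, `Sigma(0) = 0`,
  with `J = S dv/dx` and `D = S diag(v) S^T` evaluated along the mean.

The resulting negative log-likelihood

    F(theta) = - sum_i log N(nu_i; x(dt_i; theta, nu_{i-1}), Sigma(dt_i; theta))

is smooth and deterministic, so fitting is plain bounded quasi-Newton
minimisation.  Partially observed species are propagated deterministically
between intervals (their initial values can be estimated jointly), additive
Gaussian measurement noise inflates the covariance by `Sigma_meas`, and a
standardised-residual check `r_i = Sigma_i^{-1/2}(x(dt_i) - nu_i) ~ N(0, I)`
diagnoses the quality of the Gaussian approximation after the fit.

The package ships exact Gillespie simulation for data generation, three
classic benchmark networks (immigration-death, a prokaryotic
auto-regulatory gene network, stochastic Lotka-Volterra), the analytic
immigration-death transition law as an exact-likelihood oracle, and a
replicated simulation-study harness (`av` / `ARE` / `medRE` / `div`
statistics, external-estimate ranking).  See `docs/methods.md` for the
full model description and numerical choices.

## Worked example

Estimate both rates of an immigration-death process (influx `theta1`,
per-capita decay `theta2`) from one simulated series of 101 observations,
10 time units apart, starting at the deterministic steady state:

```python
import numpy as np
from mssfit import (build_immigration_death, gillespie_simulate, estimate,
                    normality_check)

net = build_immigration_death()
theta_true = [0.6, 0.06]
t_grid = 10.0 * np.arange(101)
data = gillespie_simulate(net, x0=[10], t_grid=t_grid, theta=theta_true, seed=1)

res = estimate(data, net, init_theta=[1.0, 0.1])
print(res.summary())
for c in normality_check(res.residuals()):
    print(f"{c.species}: KS={c.statistic:.3f} p={c.pvalue:.3f} -> "
          f"{'pass' if c.passed else 'fail'}")
```

prints

```
Multiple-shooting estimation results
========================================
  theta1           0.591608
  theta2          0.0528918
----------------------------------------
  -log L            242.829
  converged    True
  iterations   12  (nfev 45)
  message      CONVERGENCE: RELATIVE REDUCTION OF F <= FACTR*EPSMCH
X: KS=0.048 p=0.965 -> pass
```

The estimate `(0.59, 0.053)` sits within the typical single-series spread
around the truth `(0.6, 0.06)` — on this design the replicate-averaged
relative error is about 16% per parameter — and the Kolmogorov-Smirnov
check on the 100 standardised residuals finds them compatible with
N(0, 1), i.e. the Gaussian transition approximation is adequate here.
Note that a *single* series suffices for an estimate; replicates are only
needed to characterise the estimator.

The same machinery is scriptable from the shell:

```bash
mss simulate --model immigration_death --theta 0.6,0.06 --x0 10 \
    --n-points 101 --dt 10 --seed 1 --out data.csv
mss estimate --data data.csv --theta0 1.0,0.1
mss check --data data.csv --theta 0.6,0.06
mss study --config scenario.yaml --out-dir out/
```

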