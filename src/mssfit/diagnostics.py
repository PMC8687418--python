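"""Approximation diagnostics and the exact immigration-death oracle.

The residual check inverts the Gaussian transition approximation: if the
approximation holds, the standardised one-step deviations

    r_i = (Sigma_i^obs + Sigma_meas)^{-1/2} (x(dt_i) - nu_i)

are i.i.d. standard normal, component-wise.  The check is a necessary-style
criterion and known to be conservative: estimation can succeed even where it
fails, because the covariance only acts as a weighting factor.

The immigration-death process admits a closed-form transition law -- a
binomial thinning of the survivors convolved with Poisson immigration --
which serves both as an independent oracle for the LNA moments (they are
exact for linear propensities) and as an exact maximum-likelihood estimator
for benchmarking.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from scipy.optimize import minimize

from .networks import ReactionNetwork
from .timeseries import TimeSeries
from .lna import FAST, IntegratorOptions, regularize_covariance
from .likelihood import ObservationModel, interval_predictions
from .model import MSSResults

__all__ = [
    "ResidualSeries",
    "ComponentCheck",
    "approximation_residuals",
    "normality_check",
    "exact_id_transition_pmf",
    "exact_id_transition_logpmf",
    "exact_id_loglik",
    "exact_id_mle",
]


@dataclass
class ResidualSeries:
    """Standardised residuals (n x d) with species labels."""

    r: np.ndarray
    species_names: list

    @property
    def n(self) -> int:
        return self.r.shape[0]


@dataclass
class ComponentCheck:
    species: str
    statistic: float
    pvalue: float
    passed: bool
    sample_mean: float
    sample_var: float


def _inv_sqrt(cov: np.ndarray, interval: int) -> np.ndarray:
    """Symmetric (eigendecomposition) inverse square root of a covariance."""
    cov = regularize_covariance(cov)
    w, U = np.linalg.eigh(cov)
    if np.min(w) <= 0:
        raise np.linalg.LinAlgError(
            f"covariance of interval {interval} singular after regularisation"
        )
    return (U / np.sqrt(w)) @ U.T


def approximation_residuals(
    ts_obs: TimeSeries,
    net: ReactionNetwork,
    theta,
    obs_model: ObservationModel = None,
    nu0_hid=None,
    sigma=None,
    options: IntegratorOptions = FAST,
) -> ResidualSeries:
    """Standardised one-step prediction residuals (approximation validity check).

    One row per measurement interval (n rows for n+1 measurements); under the
    Gaussian transition approximation each component series is N(0, 1).
    """
    if obs_model is None:
        obs_model = ObservationModel.fully_observed(net)
    data, means, covs, _ = interval_predictions(
        ts_obs, net, theta, obs_model=obs_model, nu0_hid=nu0_hid, options=options
    )
    sm = obs_model.noise_cov(sigma)
    n, d = data.shape
    r = np.empty((n, d))
    for i in range(n):
        W = _inv_sqrt(covs[i] + sm, i)
        r[i] = W @ (means[i] - data[i])
    names = [net.species_names[k] for k in obs_model.obs_idx]
    return ResidualSeries(r, names)


def normality_check(rs: ResidualSeries, level: float = 0.01) -> list:
    """Per-component one-sample Kolmogorov-Smirnov test against N(0, 1)."""
    if rs.n < 5:
        raise ValueError("need at least 5 residual rows for the normality check")
    out = []
    for k, name in enumerate(rs.species_names):
        col = rs.r[:, k]
        stat, p = stats.kstest(col, "norm")
        out.append(
            ComponentCheck(
                species=name,
                statistic=float(stat),
                pvalue=float(p),
                passed=bool(p >= level),
                sample_mean=float(np.mean(col)),
                sample_var=float(np.var(col, ddof=1)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# exact immigration-death transition law
# ---------------------------------------------------------------------------

def _id_thinning_params(theta, dt):
    th1, th2 = float(theta[0]), float(theta[1])
    if th1 < 0 or th2 < 0:
        raise ValueError("immigration-death rates must be non-negative")
    if th2 == 0.0:
        return 1.0, th1 * dt  # no death: survivors all kept, Poisson(th1*dt) influx
    p = np.exp(-th2 * dt)
    lam = th1 / th2 * (1.0 - p)
    return p, lam


def exact_id_transition_pmf(n0: int, theta, dt: float, tail: float = 1e-12):
    """Exact transition pmf of the immigration-death process.

    Survivors are Binomial(n0, e^{-theta2 dt}); immigrants are
    Poisson(theta1/theta2 (1 - e^{-theta2 dt})); the transition law is their
    convolution.  Returns ``(support, pmf)`` truncated where the upper tail
    mass drops below ``tail``.
    """
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    p, lam = _id_thinning_params(theta, dt)
    b = stats.binom.pmf(np.arange(n0 + 1), n0, p)
    if lam == 0.0:
        pois = np.array([1.0])
    else:
        hi = int(stats.poisson.ppf(1.0 - tail, lam)) + 2
        pois = stats.poisson.pmf(np.arange(hi + 1), lam)
    pmf = np.convolve(b, pois)
    # trim the far tail but keep total mass within `tail` of one
    keep = np.nonzero(pmf > 0)[0]
    cum = np.cumsum(pmf)
    last = int(np.searchsorted(cum, 1.0 - tail)) + 1
    last = max(last, keep[-1] + 1 if keep.size else 1)
    pmf = pmf[:last]
    return np.arange(pmf.size), pmf


def exact_id_transition_logpmf(x: int, n0: int, theta, dt: float) -> float:
    """Exact log transition probability (analytic term, no truncation)."""
    x = int(round(x))
    if x < 0:
        return -np.inf
    p, lam = _id_thinning_params(theta, dt)
    k = np.arange(0, min(n0, x) + 1)
    terms = stats.binom.logpmf(k, n0, p) + stats.poisson.logpmf(x - k, lam)
    return float(logsumexp(terms))


def exact_id_loglik(ts: TimeSeries, theta) -> float:
    """Exact log-likelihood of a 1-species immigration-death series.

    Vectorised over intervals: the convolution sum over survivor counts k is
    evaluated as a padded (n, K+1) table (impossible k contribute -inf).
    """
    if ts.states.shape[1] != 1:
        raise ValueError("exact likelihood applies to the 1-species model only")
    x = np.asarray(np.round(ts.states[:, 0]), dtype=int)
    n0s = x[:-1]
    xs = x[1:]
    dts = ts.dts
    th1, th2 = float(theta[0]), float(theta[1])
    if th2 == 0.0:
        p = np.ones_like(dts)
        lam = th1 * dts
    else:
        p = np.exp(-th2 * dts)
        lam = th1 / th2 * (1.0 - p)
    K = int(min(n0s.max(initial=0), xs.max(initial=0)))
    k = np.arange(K + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = stats.binom.logpmf(k, n0s[:, None], p[:, None]) + stats.poisson.logpmf(
            xs[:, None] - k, lam[:, None]
        )
    terms = np.where(np.isnan(terms), -np.inf, terms)
    return float(np.sum(logsumexp(terms, axis=1)))


def exact_id_mle(
    ts: TimeSeries,
    box: tuple = (1e-6, 100.0),
    init_theta=(1.0, 0.1),
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> MSSResults:
    """Exact maximum-likelihood estimator for the immigration-death model.

    Maximises the analytic transition-law likelihood over (theta1, theta2) on
    the log scale; the result object mirrors the approximate estimators so
    study statistics can be computed uniformly.
    """
    lo, hi = box
    init_theta = np.asarray(init_theta, dtype=float)

    def fun(z):
        val = -exact_id_loglik(ts, np.exp(z))
        return val if np.isfinite(val) else 1e10

    res = minimize(
        fun,
        np.log(np.clip(init_theta, lo, hi)),
        method="L-BFGS-B",
        bounds=[(np.log(lo), np.log(hi))] * 2,
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    theta = np.exp(res.x)
    margin = 1e-6
    inside = np.all(theta > lo * (1 + margin)) and np.all(theta < hi * (1 - margin))
    grad = np.asarray(getattr(res, "jac", [np.nan]), dtype=float)
    return MSSResults(
        params=theta,
        nu0_hid=np.zeros(0),
        sigma=None,
        objective_value=float(res.fun),
        per_interval=np.array([]),
        hidden_path=np.zeros((0, 0)),
        converged=bool(res.success and inside and np.isfinite(res.fun)),
        success=bool(res.success),
        message=str(res.message),
        nit=int(res.nit),
        nfev=int(res.nfev),
        grad_norm=float(np.max(np.abs(grad))),
        n_starts=1,
        start_used=0,
        box=(lo, hi),
        model=None,
    )
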