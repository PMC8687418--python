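"""Multiple-shooting Gaussian negative log-likelihoods.

Each measurement interval is scored independently: the model is re-initialised
at the datum observed at the start of the interval (the multiple-shooting
step) and the next datum is scored under the Gaussian transition law with
ODE mean and LNA covariance.  Variants cover partially observed species
(unobserved components propagated deterministically from interval to
interval), additive Gaussian measurement noise (covariance inflated by
``Sigma_meas``), and the predecessor objective with a constant covariance
``c * I`` used for old-vs-new comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import ReactionNetwork
from .timeseries import TimeSeries
from .lna import (
    FAST,
    CovarianceError,
    IntegratorOptions,
    integrate_moments_batch,
    _triu_indices,
    _unpack,
)

try:  # compiled sequential chain (hidden-state propagation)
    from ._kernels import network_tables as _network_tables
    from ._kernels import rk4_chain as _rk4_chain_compiled
except Exception:  # pragma: no cover - numba unavailable
    _rk4_chain_compiled = None

__all__ = [
    "ObservationModel",
    "ObjectiveValue",
    "interval_predictions",
    "mss_objective",
    "mss_objective_partial",
    "mss_objective_noise",
    "constant_variance_objective",
]


@dataclass
class ObservationModel:
    """Which species are observed and with what measurement-noise covariance.

    ``obs_idx`` holds network species indices in the column order of the
    observed series.  ``sigma_meas`` is a d x d symmetric PSD matrix, a scalar
    standard deviation (expanded to ``sigma^2 I``), or None for noise-free
    observation.  ``noise_std_estimable`` marks the noise s.d. as an extra
    free parameter of the fit.
    """

    obs_idx: list
    sigma_meas: np.ndarray = None
    noise_std_estimable: bool = False

    def __post_init__(self):
        self.obs_idx = list(self.obs_idx)
        if len(set(self.obs_idx)) != len(self.obs_idx):
            raise ValueError("obs_idx must not contain duplicates")
        if self.sigma_meas is not None:
            sm = np.asarray(self.sigma_meas, dtype=float)
            if sm.ndim == 0:
                sm = float(sm) ** 2 * np.eye(len(self.obs_idx))
            if sm.shape != (len(self.obs_idx), len(self.obs_idx)):
                raise ValueError("sigma_meas must be d x d for d observed species")
            if not np.allclose(sm, sm.T):
                raise ValueError("sigma_meas must be symmetric")
            if np.min(np.linalg.eigvalsh(sm)) < -1e-10:
                raise ValueError("sigma_meas must be positive semi-definite")
            self.sigma_meas = sm

    @classmethod
    def fully_observed(cls, net: ReactionNetwork) -> "ObservationModel":
        return cls(list(range(net.n_species)))

    def hidden_idx(self, net: ReactionNetwork) -> list:
        return [i for i in range(net.n_species) if i not in self.obs_idx]

    def noise_cov(self, sigma=None) -> np.ndarray:
        d = len(self.obs_idx)
        if sigma is not None:
            return float(sigma) ** 2 * np.eye(d)
        if self.sigma_meas is None:
            return np.zeros((d, d))
        return self.sigma_meas


@dataclass
class ObjectiveValue:
    """Negative log-likelihood with its per-interval decomposition."""

    value: float
    per_interval: np.ndarray
    hidden_path: np.ndarray  # (n, D-d); row i is the hidden part of nu~_i

    def __float__(self):
        return float(self.value)


def interval_predictions(
    ts_obs: TimeSeries,
    net: ReactionNetwork,
    theta,
    obs_model: ObservationModel = None,
    nu0_hid=None,
    options: IntegratorOptions = FAST,
):
    """Per-interval predicted observed means/covariances and data.

    Returns ``(data_obs, means_obs, covs_obs, hidden_path)`` with shapes
    (n, d), (n, d), (n, d, d), (n, D-d).  With hidden species the intervals
    are propagated sequentially: the initial state of interval i combines the
    observed datum at t_{i-1} with the hidden part of the previous interval's
    mean solution.
    """
    theta = net.check_theta(theta)
    if obs_model is None:
        obs_model = ObservationModel.fully_observed(net)
    obs = np.asarray(obs_model.obs_idx, dtype=int)
    hid = np.asarray(obs_model.hidden_idx(net), dtype=int)
    D = net.n_species
    states = np.asarray(ts_obs.states, dtype=float)
    if states.shape[1] != obs.size:
        raise ValueError(
            "observed series must have one column per entry of obs_idx"
        )
    dts = ts_obs.dts
    n = ts_obs.n_intervals
    data_obs = states[1:]

    if hid.size == 0:
        means, covs = integrate_moments_batch(
            net, states[:-1], theta, dts, options=options
        )
        return data_obs, means, covs, np.zeros((n, 0))

    if nu0_hid is None:
        raise ValueError("nu0_hid is required when species are hidden")
    nu0_hid = np.atleast_1d(np.asarray(nu0_hid, dtype=float))
    if nu0_hid.shape != (hid.size,):
        raise ValueError("nu0_hid must match the number of hidden species")
    if np.any(nu0_hid < 0):
        raise ValueError("nu0_hid must be non-negative")

    if _rk4_chain_compiled is not None and options.method == "rk4":
        tb = _network_tables(net)
        iu = _triu_indices(D)
        means, covs_packed, hidden_path = _rk4_chain_compiled(
            np.ascontiguousarray(states),
            nu0_hid,
            obs.astype(np.int64),
            hid.astype(np.int64),
            np.ascontiguousarray(dts),
            options.n_steps,
            tb["S"],
            theta[tb["param_idx"]],
            tb["n_fac"],
            tb["fac_sp"],
            tb["fac_co"],
            tb["fac_off"],
            tb["fac_sg"],
            tb["inv_vol"],
            iu[0].astype(np.int64),
            iu[1].astype(np.int64),
        )
        if not (np.all(np.isfinite(means)) and np.all(np.isfinite(covs_packed))):
            from .lna import MomentIntegrationError

            raise MomentIntegrationError(
                "moment integration produced non-finite values"
            )
        covs = _unpack(covs_packed, D, iu)
        return (
            data_obs,
            means[:, obs],
            covs[np.ix_(np.arange(n), obs, obs)],
            hidden_path,
        )

    means_obs = np.empty((n, obs.size))
    covs_obs = np.empty((n, obs.size, obs.size))
    hidden_path = np.empty((n, hid.size))
    nu_tilde = np.empty(D)
    nu_tilde[obs] = states[0]
    nu_tilde[hid] = nu0_hid
    for i in range(n):
        hidden_path[i] = nu_tilde[hid]
        mean, cov = integrate_moments_batch(
            net, nu_tilde[None, :], theta, dts[i : i + 1], options=options
        )
        means_obs[i] = mean[0][obs]
        covs_obs[i] = cov[0][np.ix_(obs, obs)]
        if i + 1 < n:
            nu_tilde = np.empty(D)
            nu_tilde[obs] = states[i + 1]
            nu_tilde[hid] = mean[0][hid]
    return data_obs, means_obs, covs_obs, hidden_path


def _gaussian_neglog(data, means, covs, sigma_meas=None):
    """Per-interval Gaussian -log density, batched Cholesky with PSD jitter."""
    n, d = data.shape
    C = covs.copy()
    if sigma_meas is not None:
        C = C + sigma_meas[None, :, :]
    C = 0.5 * (C + np.swapaxes(C, 1, 2))
    evals = np.linalg.eigvalsh(C)
    tr = np.trace(C, axis1=1, axis2=2)
    eps = 1e-8 * np.maximum(1.0, tr / d)
    bad = evals[:, 0] < eps
    if np.any(bad):
        C[bad] += eps[bad, None, None] * np.eye(d)[None]
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        # name the first offending interval for the caller
        for i in range(n):
            try:
                np.linalg.cholesky(C[i])
            except np.linalg.LinAlgError as exc:
                raise CovarianceError(
                    f"covariance of interval {i} not positive definite "
                    "after regularisation"
                ) from exc
        raise
    dev = (data - means)[:, :, None]
    z = np.linalg.solve(L, dev)[:, :, 0]
    logdet = np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    return 0.5 * d * np.log(2.0 * np.pi) + logdet + 0.5 * np.sum(z * z, axis=1)


def mss_objective(
    ts: TimeSeries,
    net: ReactionNetwork,
    theta,
    options: IntegratorOptions = FAST,
) -> ObjectiveValue:
    """Extended multiple-shooting objective for a fully observed series.

    ``F = -sum_i log N(nu_i; x(dt_i; theta, nu_{i-1}), Sigma(dt_i; theta))``
    with every interval re-initialised at the preceding datum.
    """
    data, means, covs, hp = interval_predictions(
        ts, net, theta, options=options
    )
    per = _gaussian_neglog(data, means, covs)
    return ObjectiveValue(float(np.sum(per)), per, hp)


def mss_objective_partial(
    ts_obs: TimeSeries,
    net: ReactionNetwork,
    theta,
    nu0_hid=None,
    obs_model: ObservationModel = None,
    options: IntegratorOptions = FAST,
) -> ObjectiveValue:
    """Partially observed objective with deterministic hidden-state propagation.

    The density is evaluated on the observed marginal mean and covariance
    block; hidden components enter only through the interval-to-interval
    propagation of the mean solution (and the free initial value ``nu0_hid``).
    Reduces exactly to :func:`mss_objective` when all species are observed.
    """
    data, means, covs, hp = interval_predictions(
        ts_obs, net, theta, obs_model=obs_model, nu0_hid=nu0_hid, options=options
    )
    per = _gaussian_neglog(data, means, covs)
    return ObjectiveValue(float(np.sum(per)), per, hp)


def mss_objective_noise(
    ts_obs: TimeSeries,
    net: ReactionNetwork,
    theta,
    nu0_hid=None,
    obs_model: ObservationModel = None,
    sigma=None,
    options: IntegratorOptions = FAST,
) -> ObjectiveValue:
    """Measurement-noise objective: observed covariance inflated by Sigma_meas.

    Intervals are still re-initialised at the (noisy) data point, which acts
    as a simple state estimate.  ``sigma`` overrides the observation model's
    noise level with ``sigma^2 I`` (used when the noise s.d. is estimated).
    """
    if obs_model is None:
        obs_model = ObservationModel.fully_observed(net)
    data, means, covs, hp = interval_predictions(
        ts_obs, net, theta, obs_model=obs_model, nu0_hid=nu0_hid, options=options
    )
    per = _gaussian_neglog(data, means, covs, obs_model.noise_cov(sigma))
    return ObjectiveValue(float(np.sum(per)), per, hp)


def constant_variance_objective(
    ts: TimeSeries,
    net: ReactionNetwork,
    theta,
    c: float = 1.0,
    options: IntegratorOptions = FAST,
) -> ObjectiveValue:
    """Predecessor objective: Gaussian transitions with fixed covariance c*I.

    Equivalent, up to the additive constant ``n*D/2*log(2*pi*c)``, to half the
    multiple-shooting least-squares residual sum divided by ``c``; its
    minimiser therefore does not depend on ``c``.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    theta = net.check_theta(theta)
    states = np.asarray(ts.states, dtype=float)
    if states.shape[1] != net.n_species:
        raise ValueError("constant-variance objective requires a fully observed series")
    means, _ = integrate_moments_batch(
        net, states[:-1], theta, ts.dts, options=options, mean_only=True
    )
    data = states[1:]
    D = net.n_species
    dev2 = np.sum((data - means) ** 2, axis=1)
    per = 0.5 * D * np.log(2.0 * np.pi * c) + 0.5 * dev2 / c
    return ObjectiveValue(float(np.sum(per)), per, np.zeros((ts.n_intervals, 0)))
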