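"""Interval-wise transition moments via the linear noise approximation.

For a transition over one measurement interval of length ``dt`` started at the
previous datum, the transition law is approximated as Gaussian with

* mean: the deterministic rate-equation solution ``x(dt)`` from that datum,
* covariance: the solution of ``dSigma/dt = J Sigma + Sigma J^T + D/Omega``
  with ``Sigma(0) = 0``, where the Jacobian ``J`` and diffusion ``D`` are
  evaluated along the evolving mean ``x(t)``.

Two integration back ends are provided: an adaptive stiff-capable reference
(``scipy.integrate.solve_ivp``, LSODA, rtol 1e-8 / atol 1e-10) used by the
public single-interval API, and a vectorised fixed-step classical Runge-Kutta
scheme that propagates all intervals of a series in one pass (the intervals
are mutually independent thanks to the multiple-shooting re-initialisation at
each datum), which is what the likelihood machinery uses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .networks import ReactionNetwork, NetworkError, _rate_terms
from .timeseries import TimeSeries

try:  # compiled fast path; the numpy scheme below is the exact fallback
    from ._kernels import network_tables as _network_tables
    from ._kernels import rk4_batch as _rk4_batch_compiled
except Exception:  # pragma: no cover - numba unavailable
    _rk4_batch_compiled = None

__all__ = [
    "TransitionMoments",
    "IntegratorOptions",
    "MomentIntegrationError",
    "CovarianceError",
    "integrate_moments",
    "integrate_moments_batch",
    "regularize_covariance",
    "transition_logpdf",
    "approximate_simulate",
]


class MomentIntegrationError(RuntimeError):
    """Moment ODE integration failed; carries the partial state if available."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class CovarianceError(np.linalg.LinAlgError):
    """A transition covariance is not positive definite after regularisation."""


@dataclass(frozen=True)
class TransitionMoments:
    """Per-interval Gaussian transition moments (mean vector, covariance)."""

    mean: np.ndarray
    cov: np.ndarray

    def marginal(self, obs_idx) -> "TransitionMoments":
        obs_idx = np.asarray(list(obs_idx), dtype=int)
        return TransitionMoments(
            self.mean[obs_idx], self.cov[np.ix_(obs_idx, obs_idx)]
        )


@dataclass(frozen=True)
class IntegratorOptions:
    """Moment-ODE integrator configuration.

    ``method="lsoda"`` uses the adaptive reference integrator at
    (``rtol``, ``atol``); ``method="rk4"`` uses ``n_steps`` fixed classical
    Runge-Kutta steps per interval (vectorisable across intervals).
    """

    method: str = "lsoda"
    rtol: float = 1e-8
    atol: float = 1e-10
    n_steps: int = 24


FAST = IntegratorOptions(method="rk4")


def _triu_indices(D):
    return np.triu_indices(D)


def _pack(cov: np.ndarray, iu) -> np.ndarray:
    return cov[..., iu[0], iu[1]]


def _unpack(vec: np.ndarray, D, iu) -> np.ndarray:
    out = np.zeros(vec.shape[:-1] + (D, D))
    out[..., iu[0], iu[1]] = vec
    out = out + np.swapaxes(out, -1, -2)
    out[..., np.arange(D), np.arange(D)] /= 2.0
    return out


def _moment_rhs(net, theta, Y, dts, iu, mean_only=False):
    """Vectorised RHS of the stacked mean+covariance system on normalised time.

    Y has shape (n, D + T) (or (n, D) when ``mean_only``); ``dts`` rescales
    each interval to tau in [0, 1].
    """
    D = net.n_species
    X = Y[:, :D]
    V, dV = _rate_terms(net, X, theta, deriv=not mean_only)
    S = net.S
    xdot = V @ S.T
    if mean_only:
        return xdot * dts[:, None]
    J = np.einsum("dr,nri->ndi", S, dV)
    Dm = np.einsum("nr,ir,jr->nij", V, S, S) / net.volume
    Sig = _unpack(Y[:, D:], D, iu)
    Sdot = J @ Sig + Sig @ np.swapaxes(J, 1, 2) + Dm
    out = np.concatenate([xdot, _pack(Sdot, iu)], axis=1)
    return out * dts[:, None]


def integrate_moments_batch(
    net: ReactionNetwork,
    nu_prev: np.ndarray,
    theta,
    dts,
    options: IntegratorOptions = FAST,
    mean_only: bool = False,
):
    """Transition moments for a batch of intervals in one integrator pass.

    ``nu_prev`` is (n, D) initial states, ``dts`` the (n,) interval lengths.
    Returns ``(means, covs)`` with shapes (n, D) and (n, D, D) (``covs`` is
    None when ``mean_only``).
    """
    theta = net.check_theta(theta)
    nu_prev = np.atleast_2d(np.asarray(nu_prev, dtype=float))
    dts = np.broadcast_to(np.asarray(dts, dtype=float), (nu_prev.shape[0],)).copy()
    if np.any(dts < 0):
        raise ValueError("interval lengths must be non-negative")
    D = net.n_species
    iu = _triu_indices(D)
    T = 0 if mean_only else len(iu[0])
    Y0 = np.concatenate([nu_prev, np.zeros((nu_prev.shape[0], T))], axis=1)

    if options.method == "rk4":
        if _rk4_batch_compiled is not None:
            tb = _network_tables(net)
            Y = _rk4_batch_compiled(
                Y0,
                dts,
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
                mean_only,
            )
        else:
            Y = Y0
            h = 1.0 / options.n_steps
            f = lambda y: _moment_rhs(net, theta, y, dts, iu, mean_only)
            for _ in range(options.n_steps):
                k1 = f(Y)
                k2 = f(Y + 0.5 * h * k1)
                k3 = f(Y + 0.5 * h * k2)
                k4 = f(Y + h * k3)
                Y = Y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(Y)):
            raise MomentIntegrationError(
                "moment integration produced non-finite values", partial=Y
            )
    else:
        shape = Y0.shape

        def rhs(_t, y):
            return _moment_rhs(
                net, theta, y.reshape(shape), dts, iu, mean_only
            ).ravel()

        sol = solve_ivp(
            rhs,
            (0.0, 1.0),
            Y0.ravel(),
            method="LSODA",
            rtol=options.rtol,
            atol=options.atol,
        )
        if not sol.success:
            raise MomentIntegrationError(
                f"moment integration failed: {sol.message}",
                partial=sol.y[:, -1].reshape(shape) if sol.y.size else None,
            )
        Y = sol.y[:, -1].reshape(shape)

    means = Y[:, :D]
    if mean_only:
        return means, None
    covs = _unpack(Y[:, D:], D, iu)
    covs = 0.5 * (covs + np.swapaxes(covs, 1, 2))
    return means, covs


def integrate_moments(
    net: ReactionNetwork,
    nu_prev,
    theta,
    dt: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    options: IntegratorOptions = None,
) -> TransitionMoments:
    """Gaussian transition moments over a single interval of length ``dt``.

    Jointly integrates the D mean equations and the D(D+1)/2 distinct
    covariance equations from ``Sigma(0) = 0``.  ``dt = 0`` returns the
    initial conditions exactly.
    """
    nu_prev = np.asarray(nu_prev, dtype=float)
    if nu_prev.ndim == 0:
        nu_prev = nu_prev[None]
    if np.any(nu_prev < 0):
        raise NetworkError("previous state must be non-negative")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    D = net.n_species
    if dt == 0.0:
        net.check_theta(theta)
        return TransitionMoments(nu_prev.copy(), np.zeros((D, D)))
    if options is None:
        options = IntegratorOptions(method="lsoda", rtol=rtol, atol=atol)
    means, covs = integrate_moments_batch(
        net, nu_prev[None, :], theta, np.array([dt]), options=options
    )
    return TransitionMoments(means[0], covs[0])


def regularize_covariance(cov: np.ndarray) -> np.ndarray:
    """Symmetrise and, if indefinite, add a trace-scaled jitter to Sigma.

    Near-singular covariances arise legitimately (e.g. die-out intervals where
    the state sits at zero); the jitter floor keeps the Gaussian density
    evaluable without materially changing well-conditioned covariances.
    """
    cov = 0.5 * (cov + cov.T)
    D = cov.shape[0]
    eps = 1e-8 * max(1.0, np.trace(cov) / D)
    if np.min(np.linalg.eigvalsh(cov)) < eps:
        cov = cov + eps * np.eye(D)
    return cov


def transition_logpdf(
    moments: TransitionMoments,
    nu_next,
    obs_idx=None,
    sigma_meas=None,
) -> float:
    """Log Gaussian transition density at the next datum.

    Restricts to the observed marginal when ``obs_idx`` is given and inflates
    the covariance by the measurement-noise covariance ``sigma_meas``.
    Evaluated through a Cholesky factorisation for stability.
    """
    mean = np.asarray(moments.mean, dtype=float)
    cov = np.asarray(moments.cov, dtype=float)
    nu_next = np.atleast_1d(np.asarray(nu_next, dtype=float))
    full_dim = mean.size
    if obs_idx is not None:
        obs_idx = np.asarray(list(obs_idx), dtype=int)
        if obs_idx.size == 0:
            raise ValueError("obs_idx must be non-empty")
        mean = mean[obs_idx]
        cov = cov[np.ix_(obs_idx, obs_idx)]
        if nu_next.size == full_dim:
            nu_next = nu_next[obs_idx]
    d = mean.size
    if nu_next.size != d:
        raise ValueError("nu_next has wrong dimension for the observed block")
    if sigma_meas is not None:
        sigma_meas = np.asarray(sigma_meas, dtype=float)
        if sigma_meas.ndim == 0:
            sigma_meas = float(sigma_meas) * np.eye(d)
        cov = cov + sigma_meas
    cov = regularize_covariance(cov)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise CovarianceError(
            "transition covariance not positive definite after regularisation"
        ) from exc
    dev = nu_next - mean
    z = np.linalg.solve(L, dev)
    return float(
        -0.5 * d * np.log(2.0 * np.pi)
        - np.sum(np.log(np.diag(L)))
        - 0.5 * z @ z
    )


def approximate_simulate(
    net: ReactionNetwork,
    nu0,
    t_grid,
    theta,
    seed,
    options: IntegratorOptions = None,
    noise: bool = True,
    round_states: bool = True,
) -> TimeSeries:
    """Approximate trajectory sampler driven by the Gaussian transition law.

    On each interval draws the next state from N(mean, cov) conditioned on the
    previously drawn state, rounds to the nearest integer and clamps at zero
    (the jump process has non-negative integer states).  ``noise=False`` gives
    the degenerate limit: the rounded interval-wise rate-equation solution.
    """
    theta = net.check_theta(theta)
    t_grid = np.asarray(t_grid, dtype=float)
    nu0 = np.atleast_1d(np.asarray(nu0, dtype=float))
    if np.any(nu0 < 0) or not np.allclose(nu0, np.round(nu0)):
        raise NetworkError("nu0 must be a non-negative integer state")
    if options is None:
        options = IntegratorOptions(method="lsoda")
    rng = np.random.default_rng(seed)
    D = net.n_species
    out = np.empty((t_grid.size, D))
    out[0] = nu0
    x = nu0.astype(float)
    for i in range(1, t_grid.size):
        m = integrate_moments(
            net, x, theta, t_grid[i] - t_grid[i - 1], options=options
        )
        if noise:
            cov = regularize_covariance(m.cov)
            L = np.linalg.cholesky(cov)
            draw = m.mean + L @ rng.standard_normal(D)
        else:
            draw = m.mean
        if round_states:
            draw = np.maximum(np.round(draw), 0.0)
        else:
            draw = np.maximum(draw, 0.0)
        out[i] = draw
        x = draw
    return TimeSeries(
        t_grid, out, list(net.species_names), counts=round_states
    )
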