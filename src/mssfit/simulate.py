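"""Exact stochastic simulation (Gillespie direct method) on a measurement grid.

The direct method draws exponential waiting times at total rate ``a0`` and
picks the next reaction proportional to its propensity; the recorded value at
a grid time is the state immediately current there (cadlag sampling of the
jump process).  Exactness matters because these trajectories are the
ground truth of the replicated simulation studies.
"""
from __future__ import annotations

import numpy as np

from .networks import ReactionNetwork, NetworkError
from .timeseries import TimeSeries

__all__ = [
    "gillespie_simulate",
    "generate_replicates",
    "add_measurement_noise",
    "TrajectoryExplosion",
    "replicate_seed",
]

DEFAULT_MAX_EVENTS = 10**7


class TrajectoryExplosion(RuntimeError):
    """Event-count ceiling hit; carries the truncated series recorded so far."""

    def __init__(self, partial: TimeSeries, n_events: int):
        super().__init__(
            f"trajectory exceeded {n_events} reaction events before the final grid time"
        )
        self.partial = partial
        self.n_events = n_events


def _compile_propensity(net: ReactionNetwork, theta: np.ndarray):
    """Specialised single-state propensity evaluator (hot loop of the SSA)."""
    terms = []
    for rl in net.rate_laws:
        th = float(theta[rl.param_index])
        facs = [
            (f.species, np.asarray(f.coeffs)[::-1], f.offset, f.sign)
            for f in rl.factors
        ]
        terms.append((th, facs))

    def ev(x):
        out = np.empty(len(terms))
        for j, (th, facs) in enumerate(terms):
            v = th
            for sp, cdesc, off, sg in facs:
                g = off + sg * x[sp]
                acc = 0.0
                for c in cdesc:
                    acc = acc * g + c
                v *= acc
            out[j] = v
        return out

    return ev


def gillespie_simulate(
    net: ReactionNetwork,
    x0,
    t_grid,
    theta,
    seed,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> TimeSeries:
    """Exact direct-method SSA trajectory sampled at ``t_grid``.

    Deterministic for a given ``seed``.  If every propensity is zero the state
    simply stays constant.  Raises :class:`TrajectoryExplosion` when more than
    ``max_events`` reactions occur before the final grid time.
    """
    theta = net.check_theta(theta)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    x = np.asarray(x0)
    if x.shape != (net.n_species,):
        raise NetworkError(f"x0 must have length {net.n_species}")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise NetworkError("x0 must be a non-negative integer state")
    x = np.asarray(np.round(x), dtype=np.int64)

    rng = np.random.default_rng(seed)
    prop = _compile_propensity(net, theta)
    S = net.S
    out = np.empty((t_grid.size, net.n_species), dtype=np.int64)
    t = t_grid[0]
    i_grid = 0
    out[0] = x
    i_grid = 1
    n_events = 0
    while i_grid < t_grid.size:
        v = prop(x)
        a0 = v.sum()
        if a0 <= 0.0:
            out[i_grid:] = x
            break
        t_event = t + rng.exponential(1.0 / a0)
        while i_grid < t_grid.size and t_grid[i_grid] < t_event:
            out[i_grid] = x
            i_grid += 1
        if i_grid >= t_grid.size:
            break
        u = rng.random() * a0
        j = int(np.searchsorted(np.cumsum(v), u))
        j = min(j, net.n_reactions - 1)
        x = x + S[:, j]
        t = t_event
        n_events += 1
        if n_events > max_events:
            partial = TimeSeries(
                t_grid[:i_grid], out[:i_grid], list(net.species_names)
            )
            raise TrajectoryExplosion(partial, n_events)
    return TimeSeries(t_grid, out, list(net.species_names))


def replicate_seed(base_seed: int, i: int) -> int:
    """Fixed base-seed -> replicate-seed derivation (replicates re-runnable alone)."""
    return int(base_seed) + int(i)


def generate_replicates(
    net: ReactionNetwork,
    x0,
    t_grid,
    theta,
    n_rep: int,
    base_seed: int,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> list:
    """``n_rep`` independent SSA series with per-replicate derived seeds."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    return [
        gillespie_simulate(
            net, x0, t_grid, theta, replicate_seed(base_seed, i), max_events
        )
        for i in range(n_rep)
    ]


def add_measurement_noise(ts: TimeSeries, sigma, seed) -> TimeSeries:
    """Add i.i.d. zero-mean Gaussian measurement noise to every observation.

    ``sigma`` is a scalar standard deviation or a d x d covariance matrix.
    Returns a float-valued series (noisy data are no longer counts).
    """
    rng = np.random.default_rng(seed)
    states = np.asarray(ts.states, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 0:
        noisy = states + float(sigma) * rng.standard_normal(states.shape)
    else:
        L = np.linalg.cholesky(sigma)
        noisy = states + rng.standard_normal(states.shape) @ L.T
    return TimeSeries(ts.times, noisy, list(ts.species_names), counts=False)
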