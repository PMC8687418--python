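"""Replicated simulation studies: generate -> estimate -> summarise.

A ``Scenario`` fixes the ground truth (model, true parameters, measurement
grid, observation scheme, noise level) and the estimator variant;
``run_study`` simulates ``n_replicates`` independent exact trajectories,
estimates each one, and reports the replicate statistics used throughout the
benchmarks:

* ``av``    -- mean of the converged estimates, per parameter,
* ``ARE``   -- mean relative error ``|theta_hat - theta0| / theta0``,
* ``medRE`` -- median relative error,
* ``div``   -- number of non-converging replicates (excluded from the stats).

Everything derives deterministically from ``base_seed`` so that any single
replicate can be re-run in isolation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .networks import get_model
from .timeseries import TimeSeries
from .simulate import (
    DEFAULT_MAX_EVENTS,
    TrajectoryExplosion,
    gillespie_simulate,
    add_measurement_noise,
    replicate_seed,
)
from .likelihood import ObservationModel
from .model import DEFAULT_BOX, estimate, estimate_partial
from .diagnostics import exact_id_mle

__all__ = [
    "Scenario",
    "StudySummary",
    "run_study",
    "summarize_estimates",
    "rank_external",
    "scatter_report",
    "classify_trajectory",
    "scenario_from_dict",
    "scenario_from_file",
]

# seed stream offsets (kept small so derived seeds stay below 2**31)
_NOISE_OFFSET = 500_000
_START_OFFSET = 900_000


class Scenario:
    """Configuration of one replicated estimation study."""

    def __init__(
        self,
        model: str,
        theta_true,
        n_points: int,
        dt: float,
        x0=None,  # explicit state vector or "steady_state"
        model_args: dict = None,
        obs_idx: list = None,  # None -> fully observed
        hidden_init: str = "estimate",  # or "known" (hidden initial fixed)
        noise_sigma: float = 0.0,
        estimate_sigma: bool = False,
        n_replicates: int = 100,
        base_seed: int = 0,
        estimator: str = "extended",  # | "constant_variance" | "exact_id"
        box: tuple = DEFAULT_BOX,
        const_c: float = 1.0,
        trajectory_class: str = None,  # None | "normal" | "die-out" | "explode"
        explode_threshold: float = 1e4,
        max_events: int = DEFAULT_MAX_EVENTS,
        fit_options: dict = None,
    ):
        self.model = model
        self.theta_true = np.asarray(theta_true, dtype=float)
        self.n_points = int(n_points)
        self.dt = float(dt)
        self.x0 = x0
        self.model_args = dict(model_args or {})
        self.obs_idx = list(obs_idx) if obs_idx is not None else None
        self.hidden_init = hidden_init
        self.noise_sigma = float(noise_sigma)
        self.estimate_sigma = bool(estimate_sigma)
        self.n_replicates = int(n_replicates)
        self.base_seed = int(base_seed)
        self.estimator = estimator
        self.box = tuple(box)
        self.const_c = float(const_c)
        self.trajectory_class = trajectory_class
        self.explode_threshold = float(explode_threshold)
        self.max_events = int(max_events)
        self.fit_options = dict(fit_options or {})
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.estimator not in ("extended", "constant_variance", "exact_id"):
            raise ValueError(f"unknown estimator variant {self.estimator!r}")

    def network(self):
        return get_model(self.model, **self.model_args)

    def t_grid(self) -> np.ndarray:
        return self.dt * np.arange(self.n_points)

    def resolve_x0(self, net) -> np.ndarray:
        if isinstance(self.x0, str) and self.x0 == "steady_state":
            if self.model != "immigration_death":
                raise ValueError(
                    "steady_state initial rule is defined for immigration_death"
                )
            return np.array([int(round(self.theta_true[0] / self.theta_true[1]))])
        if self.x0 is None:
            raise ValueError("scenario needs an explicit x0 (or 'steady_state')")
        return np.asarray(self.x0, dtype=int)


@dataclass
class StudySummary:
    """Replicate estimates and their summary statistics."""

    estimates: np.ndarray  # n_rep x p (NaN rows for failed replicates)
    converged: np.ndarray  # boolean mask
    theta_true: np.ndarray
    param_names: list
    av: np.ndarray
    are: np.ndarray
    medre: np.ndarray
    div: int
    extra: dict = field(default_factory=dict)

    @property
    def n_converged(self) -> int:
        return int(np.sum(self.converged))

    def relative_errors(self) -> np.ndarray:
        """Componentwise relative errors of the converged estimates."""
        est = self.estimates[self.converged]
        return np.abs(est - self.theta_true) / self.theta_true

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "true": self.theta_true,
                "av": self.av,
                "ARE": self.are,
                "medRE": self.medre,
            },
            index=self.param_names,
        )
        df.index.name = "parameter"
        return df


def summarize_estimates(
    estimates, theta_true, param_names=None, converged=None, extra=None
) -> StudySummary:
    """Assemble av / ARE / medRE / div from a replicate estimate matrix."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    theta_true = np.asarray(theta_true, dtype=float)
    n_rep, p = estimates.shape
    if converged is None:
        converged = np.all(np.isfinite(estimates), axis=1)
    converged = np.asarray(converged, dtype=bool)
    if param_names is None:
        param_names = [f"theta{i+1}" for i in range(p)]
    ok = estimates[converged]
    if ok.shape[0]:
        av = ok.mean(axis=0)
        rel = np.abs(ok - theta_true) / theta_true
        are = rel.mean(axis=0)
        medre = np.median(rel, axis=0)
    else:
        av = np.full(p, np.nan)
        are = np.full(p, np.nan)
        medre = np.full(p, np.nan)
    return StudySummary(
        estimates=estimates,
        converged=converged,
        theta_true=theta_true,
        param_names=list(param_names),
        av=av,
        are=are,
        medre=medre,
        div=int(n_rep - converged.sum()),
        extra=dict(extra or {}),
    )


def classify_trajectory(
    ts: TimeSeries, explode_threshold: float = 1e4, truncated: bool = False
) -> str:
    """Trichotomy for stochastic predator-prey realisations.

    "die-out": every species hits zero simultaneously before the horizon
    (an absorbing state); "explode": the event ceiling was hit or any count
    exceeds ``explode_threshold``; "normal" otherwise.
    """
    if truncated or np.any(ts.states > explode_threshold):
        return "explode"
    if np.any(np.all(ts.states == 0, axis=1)):
        return "die-out"
    return "normal"


def _generate_series(sc: Scenario, net, x0, t_grid, i: int):
    """Replicate i's trajectory (honouring the trajectory-class filter)."""
    if sc.trajectory_class is None:
        seed = replicate_seed(sc.base_seed, i)
        try:
            return gillespie_simulate(
                net, x0, t_grid, sc.theta_true, seed, max_events=sc.max_events
            ), seed
        except TrajectoryExplosion as exc:
            return exc.partial, seed
    # scan the seed stream until the i-th trajectory of the requested class
    found = -1
    attempt = 0
    while True:
        seed = replicate_seed(sc.base_seed, attempt)
        attempt += 1
        truncated = False
        try:
            ts = gillespie_simulate(
                net, x0, t_grid, sc.theta_true, seed, max_events=sc.max_events
            )
        except TrajectoryExplosion as exc:
            ts, truncated = exc.partial, True
        if classify_trajectory(ts, sc.explode_threshold, truncated) == sc.trajectory_class:
            found += 1
            if found == i:
                return ts, seed
        if attempt > 1000 * sc.n_replicates + 1000:
            raise RuntimeError(
                f"could not find enough {sc.trajectory_class!r} trajectories"
            )


def _estimate_one(sc: Scenario, net, ts: TimeSeries, x0, i: int):
    rng = np.random.default_rng(sc.base_seed + _START_OFFSET + i)
    lo, hi = sc.box
    init = np.clip(
        sc.theta_true * rng.uniform(0.5, 2.0, size=sc.theta_true.size), lo, hi
    )
    if sc.noise_sigma:
        ts = add_measurement_noise(
            ts, sc.noise_sigma, sc.base_seed + _NOISE_OFFSET + i
        )
    if sc.estimator == "exact_id":
        return exact_id_mle(ts, box=sc.box, init_theta=init)
    if sc.estimator == "constant_variance":
        opts = {"objective": "const", "const_c": sc.const_c, **sc.fit_options}
        return estimate(ts, net, init_theta=init, box=sc.box, options=opts)
    # extended MSS
    opts = dict(sc.fit_options)
    if sc.estimate_sigma:
        opts["estimate_sigma"] = True
    if sc.obs_idx is None:
        obs_model = ObservationModel.fully_observed(net)
        if sc.noise_sigma and not sc.estimate_sigma:
            obs_model.sigma_meas = sc.noise_sigma**2 * np.eye(net.n_species)
        return estimate(
            ts, net, obs_model=obs_model, init_theta=init, box=sc.box, options=opts
        )
    obs_model = ObservationModel(sc.obs_idx)
    if sc.noise_sigma and not sc.estimate_sigma:
        obs_model.sigma_meas = sc.noise_sigma**2 * np.eye(len(sc.obs_idx))
    ts_obs = ts.select_species(sc.obs_idx)
    hid = obs_model.hidden_idx(net)
    hid_true = np.asarray(x0, dtype=float)[hid]
    if sc.hidden_init == "known":
        return estimate_partial(
            ts_obs, net, obs_model, init_theta=init, init_nu0_hid=hid_true,
            box=sc.box, fix_nu0_hid=True, options=opts,
        )
    init_hid = np.maximum(hid_true * rng.uniform(0.5, 2.0, size=len(hid)), 1.0)
    return estimate_partial(
        ts_obs, net, obs_model, init_theta=init, init_nu0_hid=init_hid,
        box=sc.box, options=opts,
    )


def run_study(sc: Scenario, out_dir=None, progress=False) -> StudySummary:
    """Run one replicated study; fully reproducible from ``sc.base_seed``.

    Individual replicate failures are recorded as non-converging ("div")
    rather than aborting the study.
    """
    net = sc.network()
    x0 = sc.resolve_x0(net)
    t_grid = sc.t_grid()
    p = sc.theta_true.size + (1 if sc.estimate_sigma else 0)
    names = list(net.param_names) + (["sigma"] if sc.estimate_sigma else [])
    estimates = np.full((sc.n_replicates, p), np.nan)
    converged = np.zeros(sc.n_replicates, dtype=bool)
    records = []
    for i in range(sc.n_replicates):
        ts, seed = _generate_series(sc, net, x0, t_grid, i)
        try:
            res = _estimate_one(sc, net, ts, x0, i)
            vec = np.asarray(res.params, dtype=float)
            if sc.estimate_sigma:
                vec = np.append(vec, res.sigma)
            estimates[i] = vec
            converged[i] = res.converged
            records.append(
                {
                    "replicate": i,
                    "seed": int(seed),
                    "theta_hat": [float(v) for v in vec],
                    "converged": bool(res.converged),
                    "objective": float(res.objective_value),
                }
            )
        except Exception as exc:  # replicate failure -> div
            records.append(
                {"replicate": i, "seed": int(seed), "error": str(exc)}
            )
        if progress:
            print(f"replicate {i + 1}/{sc.n_replicates} done", flush=True)
    summary = summarize_estimates(
        estimates,
        sc.theta_true if not sc.estimate_sigma else np.append(
            sc.theta_true, sc.noise_sigma
        ),
        param_names=names,
        converged=converged,
        extra={"scenario_model": sc.model, "estimator": sc.estimator},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "replicates.json", "w") as fh:
            json.dump(records, fh, indent=1)
        summary.to_frame().to_csv(out_dir / "summary.tsv", sep="\t")
    return summary


def rank_external(w, summary: StudySummary, theta_true=None) -> int:
    """Rank an external single-series estimate among the replicate estimates.

    The scalar error of an estimate is the mean of its componentwise relative
    errors.  Rank 1 means the external estimate beats every replicate; ties
    are broken in the external estimate's favour.
    """
    theta_true = np.asarray(
        summary.theta_true if theta_true is None else theta_true, dtype=float
    )
    w = np.asarray(w, dtype=float)
    if w.shape != theta_true.shape:
        raise ValueError("external estimate has wrong length")
    w_err = float(np.mean(np.abs(w - theta_true) / theta_true))
    rep_err = np.mean(
        np.abs(summary.estimates[summary.converged] - theta_true) / theta_true,
        axis=1,
    )
    return int(1 + np.sum(rep_err < w_err))


def scatter_report(summary: StudySummary, out_prefix, plot: bool = True):
    """Write the study tables (TSV) and, for 2-parameter models, the estimate cloud."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    summary.to_frame().to_csv(f"{out_prefix}_summary.tsv", sep="\t")
    est = pd.DataFrame(summary.estimates, columns=summary.param_names)
    est["converged"] = summary.converged
    est.index.name = "replicate"
    est.to_csv(f"{out_prefix}_estimates.tsv", sep="\t")
    made_plot = False
    if plot and summary.estimates.shape[1] == 2 and summary.n_converged:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ok = summary.estimates[summary.converged]
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(ok[:, 0], ok[:, 1], "k.", ms=5, label="replicate estimates")
        ax.plot(
            summary.theta_true[0],
            summary.theta_true[1],
            "o",
            color="0.6",
            ms=12,
            label="true value",
        )
        ax.set_xlabel(summary.param_names[0])
        ax.set_ylabel(summary.param_names[1])
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        fig.savefig(f"{out_prefix}_scatter.png", dpi=120)
        plt.close(fig)
        made_plot = True
    return made_plot


def scenario_from_dict(cfg: dict) -> Scenario:
    cfg = dict(cfg)
    if "box" in cfg and cfg["box"] is not None:
        cfg["box"] = tuple(cfg["box"])
    return Scenario(
        cfg.pop("model"),
        cfg.pop("theta_true"),
        cfg.pop("n_points"),
        cfg.pop("dt"),
        x0=cfg.pop("x0", None),
        **cfg,
    )


def scenario_from_file(path) -> Scenario:
    with open(path) as fh:
        text = fh.read()
    try:
        cfg = json.loads(text)
    except json.JSONDecodeError:
        cfg = yaml.safe_load(text)
    return scenario_from_dict(cfg)
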