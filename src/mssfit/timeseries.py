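"""Time-series container for discretely observed molecule counts."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """Measurements ``states[i]`` (one row per grid time) at times ``times``.

    SSA output carries non-negative integer counts; series with additive
    measurement noise carry floats (and may dip below zero), which is
    permitted when ``counts=False``.
    """

    times: np.ndarray
    states: np.ndarray
    species_names: list
    counts: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states))
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D array")
        if self.states.shape[0] != self.times.size:
            raise ValueError("states must have one row per time point")
        if len(self.species_names) != self.states.shape[1]:
            raise ValueError("species_names must match the state dimension")
        if self.counts:
            if np.any(self.states < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(self.states, np.round(self.states)):
                raise ValueError("counts must be integer-valued")
            self.states = np.asarray(np.round(self.states), dtype=np.int64)
        else:
            self.states = np.asarray(self.states, dtype=float)

    @property
    def n_intervals(self) -> int:
        return self.times.size - 1

    @property
    def dts(self) -> np.ndarray:
        return np.diff(self.times)

    def select_species(self, obs_idx) -> "TimeSeries":
        obs_idx = list(obs_idx)
        return TimeSeries(
            self.times,
            self.states[:, obs_idx],
            [self.species_names[i] for i in obs_idx],
            counts=self.counts,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species_names)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path)
        species = [c for c in df.columns if c != "time"]
        states = df[species].to_numpy()
        is_counts = bool(
            np.all(states >= 0) and np.allclose(states, np.round(states))
        )
        return cls(df["time"].to_numpy(), states, species, counts=is_counts)

    def __eq__(self, other):
        return (
            isinstance(other, TimeSeries)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.states, other.states)
            and self.species_names == other.species_names
        )
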