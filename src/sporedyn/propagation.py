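"""Exact propagation of population vectors through piecewise-constant
linear dynamics.

Within a stress phase the dynamics dN/dt = M N are linear with constant
M, so the solution is the matrix exponential N(t + dt) = exp(M dt) N(t).
A whole trajectory is a product of per-phase exponentials.  For the
repeated sweeps in the fitness experiments, :class:`PhasePropagators`
caches the eigendecomposition of each phase generator so that exp(M dt)
for many dt costs three small matrix-vector products; it falls back to
``scipy.linalg.expm`` when the eigenbasis is ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .models import (
    PHASES,
    GeneratorMatrix,
    ModelTopology,
    RateParameters,
    build_generator,
)
from .environment import StressProfile

__all__ = [
    "PopulationState",
    "Trajectory",
    "propagate_phase",
    "simulate",
    "total_population",
    "PhasePropagators",
    "initial_state",
]


@dataclass(frozen=True)
class PopulationState:
    """Continuous per-state cell counts at one time point."""

    states: tuple[str, ...]
    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.shape != (len(self.states),):
            raise ValueError("counts length must match the state list")
        if np.any(c < 0):
            raise ValueError("population counts must be nonnegative")


def initial_state(topology: ModelTopology, total: float = 1.0) -> PopulationState:
    """All cells vegetative.  Ratios are scale-invariant by linearity, so
    the total is immaterial for fitness comparisons."""
    counts = np.zeros(topology.n_states)
    counts[topology.index("V")] = total
    return PopulationState(states=topology.states, counts=counts, time=0.0)


@dataclass(frozen=True)
class Trajectory:
    """Population counts per state on an ordered time grid."""

    model: str
    states: tuple[str, ...]
    times: np.ndarray
    counts: np.ndarray  # shape (n_times, n_states)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if c.shape != (t.size, len(self.states)):
            raise ValueError("counts shape must be (n_times, n_states)")

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(self.states, self.counts[-1], float(self.times[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.states))
        df.insert(0, "time_h", self.times)
        df["total"] = self.counts.sum(axis=1)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, model: str = "") -> "Trajectory":
        df = pd.read_csv(path)
        states = tuple(c for c in df.columns if c not in ("time_h", "total"))
        return cls(
            model=model,
            states=states,
            times=df["time_h"].to_numpy(),
            counts=df[list(states)].to_numpy(),
        )


def total_population(state: PopulationState) -> float:
    """Total cell count summed over all model states."""
    return float(state.counts.sum())


def propagate_phase(n0: PopulationState, gen: GeneratorMatrix, dt: float) -> PopulationState:
    """Advance a population exactly by ``dt`` hours under one generator:
    ``exp(M dt) N0``.  ``dt = 0`` returns the state unchanged."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if n0.states != gen.states:
        raise ValueError("population and generator state sets differ")
    if dt == 0:
        return n0
    counts = expm(gen.matrix * dt) @ n0.counts
    return PopulationState(n0.states, np.maximum(counts, 0.0), n0.time + dt)


class _EigPropagator:
    """exp(M dt) x via a cached eigendecomposition of M."""

    __slots__ = ("_w", "_v", "_vinv", "_m", "_ok")

    def __init__(self, m: np.ndarray):
        self._m = m
        w, v = np.linalg.eig(m)
        self._ok = np.linalg.cond(v) < 1e8
        self._w, self._v = w, v
        self._vinv = np.linalg.inv(v) if self._ok else None

    def apply(self, x: np.ndarray, dt: float) -> np.ndarray:
        if self._ok:
            y = (self._v @ (np.exp(self._w * dt) * (self._vinv @ x))).real
        else:  # defective generator: fall back to the dense exponential
            y = expm(self._m * dt) @ x
        return np.maximum(y, 0.0)


class PhasePropagators:
    """Exact per-phase propagators for one model parameterization."""

    def __init__(self, topology: ModelTopology, params: RateParameters):
        self.topology = topology
        self.generators = {
            phase: build_generator(topology, params, phase) for phase in PHASES
        }
        self._props = {
            phase: _EigPropagator(gen.matrix) for phase, gen in self.generators.items()
        }

    def advance(self, counts: np.ndarray, phase: str, dt: float) -> np.ndarray:
        if dt == 0:
            return counts
        return self._props[phase].apply(counts, dt)

    def final_counts(self, profile: StressProfile, counts: np.ndarray) -> np.ndarray:
        for phase, dur in profile.phases:
            counts = self.advance(counts, phase, dur)
        return counts


def simulate(
    topology: ModelTopology,
    params: RateParameters,
    profile: StressProfile,
    n0: PopulationState | None = None,
    sampling_dt: float = 0.1,
) -> Trajectory:
    """Propagate a population through a stress profile.

    The trajectory is recorded on the regular ``sampling_dt`` grid plus at
    every phase boundary; the final timestamp equals the profile's total
    time.
    """
    if sampling_dt <= 0:
        raise ValueError("sampling_dt must be positive")
    if n0 is None:
        n0 = initial_state(topology)
    if n0.states != topology.states:
        raise ValueError("initial state does not match the topology")
    props = PhasePropagators(topology, params)

    total_time = profile.total_time
    grid = np.arange(0.0, total_time + sampling_dt / 2, sampling_dt)
    boundaries = np.cumsum([d for _, d in profile.phases])
    record_times = np.unique(
        np.concatenate([grid, boundaries, [0.0, total_time]]).round(12)
    )
    record_times = record_times[(record_times >= 0) & (record_times <= total_time + 1e-9)]
    # collapse near-duplicate grid/boundary times so timestamps stay strictly increasing
    keep = np.concatenate([[True], np.diff(record_times) > 1e-9])
    record_times = record_times[keep]
    record_times[-1] = total_time

    times, rows = [], []
    counts = n0.counts.copy()
    t = 0.0
    idx = 0  # next record index
    if record_times[0] == 0.0:
        times.append(0.0)
        rows.append(counts.copy())
        idx = 1
    for (phase, dur), t_end in zip(profile.phases, boundaries):
        while idx < record_times.size and record_times[idx] <= t_end + 1e-12:
            dt = record_times[idx] - t
            counts = props.advance(counts, phase, max(dt, 0.0))
            t = record_times[idx]
            times.append(t)
            rows.append(counts.copy())
            idx += 1
        if t < t_end - 1e-12:
            counts = props.advance(counts, phase, t_end - t)
            t = t_end
    return Trajectory(
        model=topology.name,
        states=topology.states,
        times=np.asarray(times),
        counts=np.vstack(rows),
    )
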