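"""Alternating high/low stress schedules.

The environment is strictly two-level ("dichotomic"): it alternates
between a high-stress and a low-stress phase.  The fraction of time spent
under high stress, f, and the mean cycle duration T_cycle parameterize
both a deterministic periodic schedule and a random telegraph schedule
whose phase durations are drawn independently (exponential by default,
memoryless switching; a uniform-duration variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StressProfile",
    "periodic_profile",
    "random_dichotomic_profile",
    "sample_stress_fractions",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class StressProfile:
    """Ordered alternating stress phases covering [0, total_time].

    ``phases`` is a tuple of ``(phase, duration_h)`` with phase in
    {"high", "low"}; durations are positive and sum to ``total_time``.
    ``f`` is the nominal high-stress fraction, ``t_cycle`` the mean cycle
    duration in hours, ``seed`` the RNG seed if the profile is random.
    """

    phases: tuple[tuple[str, float], ...]
    f: float
    t_cycle: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("a profile needs at least one phase")
        for phase, dur in self.phases:
            if phase not in ("high", "low"):
                raise ValueError(f"unknown phase {phase!r}")
            if dur <= 0:
                raise ValueError("phase durations must be positive")
        for (a, _), (b, _) in zip(self.phases, self.phases[1:]):
            if a == b:
                raise ValueError("phases must alternate")

    @property
    def total_time(self) -> float:
        return float(sum(d for _, d in self.phases))

    @property
    def high_fraction(self) -> float:
        """Realized fraction of total time spent under high stress."""
        high = sum(d for p, d in self.phases if p == "high")
        return high / self.total_time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phases, columns=["phase", "duration_h"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, f: float = float("nan"), t_cycle: float | None = None) -> "StressProfile":
        df = pd.read_csv(path)
        phases = tuple((str(p), float(d)) for p, d in zip(df["phase"], df["duration_h"]))
        prof = cls(phases=phases, f=f, t_cycle=t_cycle)
        if np.isnan(f):
            object.__setattr__(prof, "f", prof.high_fraction)
        return prof


def _single_phase(phase: str, total_time: float, f: float, t_cycle: float | None, seed=None) -> StressProfile:
    return StressProfile(phases=((phase, total_time),), f=f, t_cycle=t_cycle, seed=seed)


def periodic_profile(f: float, t_cycle: float, total_time: float) -> StressProfile:
    """Deterministic schedule repeating (high, f*T), (low, (1-f)*T) cycles.

    The last cycle is truncated at ``total_time``; f = 0 or 1 yields a
    single phase.
    """
    if not 0 <= f <= 1:
        raise ValueError(f"high-stress fraction must be in [0, 1], got {f}")
    if t_cycle <= 0 or total_time <= 0:
        raise ValueError("t_cycle and total_time must be positive")
    if f == 0:
        return _single_phase("low", total_time, f, t_cycle)
    if f == 1:
        return _single_phase("high", total_time, f, t_cycle)
    durations = {"high": f * t_cycle, "low": (1 - f) * t_cycle}
    phases: list[tuple[str, float]] = []
    t, current = 0.0, "high"
    while t < total_time - 1e-12:
        d = min(durations[current], total_time - t)
        phases.append((current, d))
        t += d
        current = "low" if current == "high" else "high"
    return StressProfile(phases=tuple(phases), f=f, t_cycle=t_cycle)


def random_dichotomic_profile(
    f: float,
    t_cycle: float,
    total_time: float,
    seed: int,
    durations: str = "exponential",
    start_phase: str | None = None,
) -> StressProfile:
    """Random telegraph stress schedule.

    Phase durations are drawn independently with mean ``f * t_cycle``
    (high) and ``(1 - f) * t_cycle`` (low): exponentially by default, or
    uniform on [0, 2 * mean] with ``durations="uniform"``.  The schedule
    starts with the phase whose expected duration is longer (override via
    ``start_phase``) and is truncated at ``total_time``.  Degenerate f
    (0 or 1) delegates to :func:`periodic_profile`.  The same seed yields
    an identical profile.
    """
    if t_cycle <= 0 or total_time <= 0:
        raise ValueError("t_cycle and total_time must be positive")
    if not 0 <= f <= 1:
        raise ValueError(f"high-stress fraction must be in [0, 1], got {f}")
    if f in (0.0, 1.0):
        prof = periodic_profile(f, t_cycle, total_time)
        return StressProfile(phases=prof.phases, f=f, t_cycle=t_cycle, seed=seed)
    if durations not in ("exponential", "uniform"):
        raise ValueError("durations must be 'exponential' or 'uniform'")
    rng = np.random.default_rng(seed)
    means = {"high": f * t_cycle, "low": (1 - f) * t_cycle}
    current = start_phase or ("high" if f >= 0.5 else "low")
    if current not in ("high", "low"):
        raise ValueError(f"unknown start phase {current!r}")
    phases: list[tuple[str, float]] = []
    t = 0.0
    while t < total_time - 1e-12:
        mean = means[current]
        d = rng.exponential(mean) if durations == "exponential" else rng.uniform(0, 2 * mean)
        d = min(max(d, 1e-9), total_time - t)
        phases.append((current, d))
        t += d
        current = "low" if current == "high" else "high"
    return StressProfile(phases=tuple(phases), f=f, t_cycle=t_cycle, seed=seed)


def sample_stress_fractions(n: int, seed: int) -> np.ndarray:
    """Draw ``n`` high-stress fractions uniformly on [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).uniform(0.0, 1.0, size=n)


def spawn_seeds(seed: int, shape) -> np.ndarray:
    """Deterministic child seeds (< 2**31) derived from a master seed."""
    return np.random.default_rng(seed).integers(0, _MAX_SEED, size=shape)
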