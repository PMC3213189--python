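"""Model-comparison experiments under fluctuating stress.

Relative fitness is the ratio of total cell counts (summed over all
states) of two models exposed to the *identical* stress schedule from the
same initial population.  Three experiments are implemented:

* a sweep of the hybrid-vs-alternatives fitness ratios over the
  high-stress fraction f, averaged over random telegraph environments;
* max-variation sensitivity envelopes under simultaneous random
  perturbation of all non-zero parameters;
* the average fitness over uniformly random high-stress fractions with
  a fixed integration horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import (
    StressProfile,
    random_dichotomic_profile,
    sample_stress_fractions,
    spawn_seeds,
)
from .models import (
    ModelTopology,
    RateParameters,
    default_parameters,
    make_topology,
)
from .propagation import (
    PhasePropagators,
    PopulationState,
    initial_state,
    total_population,
)

__all__ = [
    "FitnessCurve",
    "AverageFitnessResult",
    "model_suite",
    "fitness_ratio",
    "sweep_high_stress_fraction",
    "sensitivity_envelope",
    "random_environment_average",
]


def model_suite(
    param_sets: dict[str, RateParameters] | None = None,
) -> dict[str, tuple[ModelTopology, RateParameters]]:
    """The three decision schemes with their (default) parameterizations."""
    suite = {}
    for name in ("hybrid", "irreversible_only", "reversible_only"):
        topo = make_topology(name)
        params = (param_sets or {}).get(name) or default_parameters(topo)
        suite[name] = (topo, params)
    return suite


def _baseline_scalars() -> dict[str, float]:
    """The scalar baseline rates shared by all three models (per hour)."""
    import inspect

    sig = inspect.signature(default_parameters)
    return {
        name: p.default
        for name, p in sig.parameters.items()
        if isinstance(p.default, (int, float))
    }


def perturbed_suite(
    fraction: float, rng: np.random.Generator
) -> dict[str, tuple[ModelTopology, RateParameters]]:
    """One coherent perturbation draw of the shared baseline rates.

    The three models are parameterized from a single rate table, so a
    perturbation multiplies every non-zero baseline value (per phase) by
    an independent factor uniform in [1-p, 1+p] and rebuilds all three
    models from the same perturbed table.  Growth magnitudes are scaled;
    signs are preserved.
    """
    scalars = {
        key: value * rng.uniform(1 - fraction, 1 + fraction) if value != 0 else 0.0
        for key, value in _baseline_scalars().items()
    }
    return {
        name: (make_topology(name), default_parameters(make_topology(name), **scalars))
        for name in ("hybrid", "irreversible_only", "reversible_only")
    }


def fitness_ratio(
    topology_a: ModelTopology,
    params_a: RateParameters,
    topology_b: ModelTopology,
    params_b: RateParameters,
    profile: StressProfile,
    n0: PopulationState | None = None,
) -> float:
    """Final total population of model a divided by model b's, both run
    through the same profile from the same initial condition."""
    total_a = _final_total(topology_a, params_a, profile, n0)
    total_b = _final_total(topology_b, params_b, profile, n0)
    if total_b == 0:
        raise ZeroDivisionError(
            "model b finished with zero total population; check rates and horizon"
        )
    return total_a / total_b


def _final_total(topology, params, profile, n0=None) -> float:
    counts = (n0.counts if n0 is not None else initial_state(topology).counts).copy()
    return float(PhasePropagators(topology, params).final_counts(profile, counts).sum())


@dataclass
class FitnessCurve:
    """Hybrid-vs-alternative fitness ratios across high-stress fractions."""

    fractions: np.ndarray
    ratio_hyb_irr: np.ndarray
    ratio_hyb_rev: np.ndarray
    env_irr: tuple[np.ndarray, np.ndarray] | None = None  # (lo, hi)
    env_rev: tuple[np.ndarray, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "high_stress_fraction": self.fractions,
                "ratio_hybrid_vs_irreversible": self.ratio_hyb_irr,
                "ratio_hybrid_vs_reversible": self.ratio_hyb_rev,
            }
        )
        if self.env_irr is not None:
            df["env_irr_lo"], df["env_irr_hi"] = self.env_irr
        if self.env_rev is not None:
            df["env_rev_lo"], df["env_rev_hi"] = self.env_rev
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def summary(self) -> dict:
        return {
            "kind": "fitness_curve",
            "n_fractions": int(self.fractions.size),
            "meta": self.meta,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def _sweep_profiles(
    fractions: np.ndarray,
    t_cycle: float,
    total_time: float,
    n_realizations: int,
    seed: int,
    durations: str,
) -> list[list[StressProfile]]:
    seeds = spawn_seeds(seed, (fractions.size, n_realizations))
    return [
        [
            random_dichotomic_profile(
                f, t_cycle, total_time, int(seeds[i, r]), durations=durations
            )
            for r in range(n_realizations)
        ]
        for i, f in enumerate(fractions)
    ]


def _ratios_over_profiles(
    suite: dict[str, tuple[ModelTopology, RateParameters]],
    profiles: list[list[StressProfile]],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean hybrid/irreversible and hybrid/reversible ratios per fraction."""
    props = {name: PhasePropagators(t, p) for name, (t, p) in suite.items()}
    x0 = {name: initial_state(t).counts for name, (t, _) in suite.items()}
    r_irr = np.empty(len(profiles))
    r_rev = np.empty(len(profiles))
    for i, profs in enumerate(profiles):
        acc_irr = acc_rev = 0.0
        for prof in profs:
            totals = {
                name: props[name].final_counts(prof, x0[name].copy()).sum()
                for name in props
            }
            acc_irr += totals["hybrid"] / totals["irreversible_only"]
            acc_rev += totals["hybrid"] / totals["reversible_only"]
        r_irr[i] = acc_irr / len(profs)
        r_rev[i] = acc_rev / len(profs)
    return r_irr, r_rev


def sweep_high_stress_fraction(
    n_f: int = 100,
    total_time: float = 30.0,
    t_cycle: float = 6.0,
    n_realizations: int = 25,
    seed: int = 0,
    param_sets: dict[str, RateParameters] | None = None,
    durations: str = "exponential",
) -> FitnessCurve:
    """Fitness-ratio curves over evenly spaced high-stress fractions.

    For each of ``n_f`` fractions in (0, 1), ``n_realizations`` random
    telegraph profiles are drawn; every profile is applied to all three
    models and the per-fraction mean ratios are recorded.
    """
    if n_f < 2:
        raise ValueError("n_f must be >= 2")
    fractions = np.arange(1, n_f + 1) / (n_f + 1)
    suite = model_suite(param_sets)
    profiles = _sweep_profiles(fractions, t_cycle, total_time, n_realizations, seed, durations)
    r_irr, r_rev = _ratios_over_profiles(suite, profiles)
    return FitnessCurve(
        fractions=fractions,
        ratio_hyb_irr=r_irr,
        ratio_hyb_rev=r_rev,
        meta={
            "total_time_h": total_time,
            "t_cycle_h": t_cycle,
            "n_realizations": n_realizations,
            "seed": int(seed),
            "durations": durations,
        },
    )


def sensitivity_envelope(
    curve: FitnessCurve | None = None,
    perturbation_fraction: float = 0.2,
    n_draws: int = 100,
    perturbation_seed: int = 1,
    **sweep_kwargs,
) -> FitnessCurve:
    """Max-variation envelopes from simultaneous random parameter changes.

    Every non-zero rate and growth magnitude of every model is multiplied
    by an independent factor uniform in [1-p, 1+p]; factors are drawn once
    per draw and applied across all fractions.  The environment
    realizations are identical to the baseline sweep's, so the envelopes
    isolate parameter sensitivity.  Envelopes are the pointwise min/max
    over the draws and the baseline, hence always bracket the baseline.
    """
    if not 0 <= perturbation_fraction < 1:
        raise ValueError("perturbation_fraction must be in [0, 1)")
    if curve is None:
        curve = sweep_high_stress_fraction(**sweep_kwargs)
    meta = curve.meta
    fractions = curve.fractions
    profiles = _sweep_profiles(
        fractions,
        meta["t_cycle_h"],
        meta["total_time_h"],
        meta["n_realizations"],
        meta["seed"],
        meta.get("durations", "exponential"),
    )
    rng = np.random.default_rng(perturbation_seed)
    lo_irr, hi_irr = curve.ratio_hyb_irr.copy(), curve.ratio_hyb_irr.copy()
    lo_rev, hi_rev = curve.ratio_hyb_rev.copy(), curve.ratio_hyb_rev.copy()
    for _ in range(n_draws):
        r_irr, r_rev = _ratios_over_profiles(
            perturbed_suite(perturbation_fraction, rng), profiles
        )
        np.minimum(lo_irr, r_irr, out=lo_irr)
        np.maximum(hi_irr, r_irr, out=hi_irr)
        np.minimum(lo_rev, r_rev, out=lo_rev)
        np.maximum(hi_rev, r_rev, out=hi_rev)
    return FitnessCurve(
        fractions=fractions,
        ratio_hyb_irr=curve.ratio_hyb_irr,
        ratio_hyb_rev=curve.ratio_hyb_rev,
        env_irr=(lo_irr, hi_irr),
        env_rev=(lo_rev, hi_rev),
        meta={
            **meta,
            "perturbation_fraction": perturbation_fraction,
            "n_perturbation_draws": n_draws,
            "perturbation_seed": int(perturbation_seed),
            "perturbation_scope": "once per draw across all fractions",
        },
    )


@dataclass
class AverageFitnessResult:
    """Mean fitness of the hybrid model over random environments."""

    mean_ratio_hyb_irr: float
    mean_ratio_hyb_rev: float
    var_irr: tuple[float, float] | None  # max-variation bars (lo, hi)
    var_rev: tuple[float, float] | None
    n_fractions: int
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "kind": "average_fitness",
            "mean_ratio_hybrid_vs_irreversible": self.mean_ratio_hyb_irr,
            "mean_ratio_hybrid_vs_reversible": self.mean_ratio_hyb_rev,
            "max_variation_irr": list(self.var_irr) if self.var_irr else None,
            "max_variation_rev": list(self.var_rev) if self.var_rev else None,
            "n_fractions": self.n_fractions,
            "meta": self.meta,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def random_environment_average(
    n_fractions: int = 100,
    total_time: float = 30.0,
    t_cycle: float = 6.0,
    seed: int = 0,
    perturbation_fraction: float = 0.2,
    n_perturbation_draws: int = 100,
    param_sets: dict[str, RateParameters] | None = None,
) -> AverageFitnessResult:
    """Average fitness ratios over uniformly random high-stress fractions.

    ``n_fractions`` fractions are drawn uniformly on [0, 1]; for each, one
    random telegraph profile is generated and all three models integrated
    over ``total_time``.  The returned means are over fractions.  Max-
    variation bars come from re-running the whole protocol under +/-
    ``perturbation_fraction`` parameter perturbations (one factor set per
    draw); set ``n_perturbation_draws=0`` to skip them.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    frac_seed, prof_seed, pert_seed = (int(s) for s in spawn_seeds(seed, 3))
    fractions = sample_stress_fractions(n_fractions, frac_seed)
    prof_seeds = spawn_seeds(prof_seed, n_fractions)
    profiles = [
        [random_dichotomic_profile(f, t_cycle, total_time, int(s))]
        for f, s in zip(fractions, prof_seeds)
    ]
    suite = model_suite(param_sets)
    r_irr, r_rev = _ratios_over_profiles(suite, profiles)
    mean_irr, mean_rev = float(r_irr.mean()), float(r_rev.mean())

    var_irr = var_rev = None
    if n_perturbation_draws > 0:
        rng = np.random.default_rng(pert_seed)
        lo_i = hi_i = mean_irr
        lo_r = hi_r = mean_rev
        for _ in range(n_perturbation_draws):
            p_irr, p_rev = _ratios_over_profiles(
                perturbed_suite(perturbation_fraction, rng), profiles
            )
            lo_i, hi_i = min(lo_i, p_irr.mean()), max(hi_i, p_irr.mean())
            lo_r, hi_r = min(lo_r, p_rev.mean()), max(hi_r, p_rev.mean())
        var_irr, var_rev = (lo_i, hi_i), (lo_r, hi_r)
    return AverageFitnessResult(
        mean_ratio_hyb_irr=mean_irr,
        mean_ratio_hyb_rev=mean_rev,
        var_irr=var_irr,
        var_rev=var_rev,
        n_fractions=n_fractions,
        meta={
            "total_time_h": total_time,
            "t_cycle_h": t_cycle,
            "seed": int(seed),
            "perturbation_fraction": perturbation_fraction,
            "n_perturbation_draws": n_perturbation_draws,
            "perturbation_scope": "once per draw across all fractions",
        },
    )
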