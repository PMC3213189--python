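"""Synthetic single-cell reporter-trace cohorts with ground truth.

The generator emulates the statistical structure of sporulation reporter
movies: sporulating cells with staged onsets of the early reporters, a
sharp late-reporter rise, and a spore appearing after a tightly
distributed commitment interval; non-sporulating cells with transient
bursts of early-reporter activity; rare cells with a transient septal-
localization event; and quiescent cells.  All channels carry additive
Gaussian measurement noise.  Every cell carries its ground-truth fate and
event times, so the trace-analysis estimators can be validated by
parameter recovery.

Channel kinetics are piecewise exponential ramps (rise to plateau) — a
phenomenological stand-in for the reporter dynamics, not a mechanistic
circuit model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .traces import (
    CH_0A,
    CH_0F,
    CH_IIE,
    CH_IIR,
    CellTrace,
    commitment_intervals,
    detect_activation,
    detect_bursts,
    transient_localization_fraction,
    write_traces,
)

__all__ = ["GeneratorConfig", "Cohort", "generate_cohort", "recovery_report"]

FATES = ("sporulating", "burst_only", "transient_localization", "quiescent")


@dataclass
class GeneratorConfig:
    """Cohort generator settings (times in hours, rates per cell).

    Fate probabilities must sum to at most 1; the remainder is quiescent.
    The commitment interval (late-reporter activation to spore) and the
    cell-cycle duration are log-normal, parameterized by median and CV.
    ``noise_sd`` is the additive Gaussian noise SD as a fraction of the
    nominal channel dynamic range.
    """

    n_cells: int = 100
    sampling_dt: float = 1.0 / 3.0  # 20-minute frames
    t_total: float = 16.0
    p_sporulate: float = 0.5
    p_burst_only: float = 0.3
    p_transient_localization: float = 0.02
    # staged channel onsets relative to the cell's sporulation start
    onset_offsets: dict = field(
        default_factory=lambda: {CH_0A: 0.0, CH_0F: 0.5, CH_IIE: 1.5, CH_IIR: 3.0}
    )
    rise_tau: dict = field(
        default_factory=lambda: {CH_0A: 1.0, CH_0F: 1.0, CH_IIE: 0.5, CH_IIR: 0.01}
    )
    sporulation_start_window: tuple = (6.5, 8.5)
    commitment_median: float = 1.0
    commitment_cv: float = 0.2
    cycle_median: float = 20.0 / 3.0  # interval/cycle median ratio = 15%
    cycle_cv: float = 0.2
    activation_threshold: float = 0.6
    burst_rate: float = 2.0  # mean bursts per burst-only cell
    burst_rise_tau: float = 0.3
    burst_rise_duration: float = 0.9
    burst_decay_tau: float = 0.5
    burst_amplitude: tuple = (0.7, 1.0)
    localization_duration: tuple = (0.5, 1.5)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_sporulate, self.p_burst_only, self.p_transient_localization)
        if any(p < 0 or p > 1 for p in probs) or sum(probs) > 1 + 1e-12:
            raise ValueError("fate probabilities must lie in [0, 1] and sum to <= 1")
        if self.commitment_cv <= 0 or self.cycle_cv <= 0:
            raise ValueError("distribution CVs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.burst_rate < 1:
            raise ValueError("burst_rate must be >= 1 (burst-only cells burst at least once)")

    @property
    def p_quiescent(self) -> float:
        return 1.0 - self.p_sporulate - self.p_burst_only - self.p_transient_localization

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("sporulation_start_window", "burst_amplitude", "localization_duration"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class Cohort:
    """Generated traces plus their ground-truth event table."""

    traces: list[CellTrace]
    truth: pd.DataFrame  # cell_id, fate, event, time_h
    config: GeneratorConfig

    def write(self, trace_path, annotation_path, truth_path=None) -> None:
        write_traces(self.traces, trace_path, annotation_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False, float_format="%.9g")


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=math.log(median), sigma=sigma))


def _ramp(times: np.ndarray, onset: float, tau: float, amplitude: float) -> np.ndarray:
    s = np.maximum(times - onset, 0.0)
    return amplitude * (1.0 - np.exp(-s / tau)) * (times >= onset)


def _pulse(times, start, amplitude, rise_tau, rise_duration, decay_tau):
    """Exponential rise to near-plateau, then exponential decay."""
    x = np.zeros_like(times)
    rising = (times >= start) & (times < start + rise_duration)
    x[rising] = amplitude * (1.0 - np.exp(-(times[rising] - start) / rise_tau))
    peak = amplitude * (1.0 - math.exp(-rise_duration / rise_tau))
    decaying = times >= start + rise_duration
    x[decaying] = peak * np.exp(-(times[decaying] - start - rise_duration) / decay_tau)
    return x


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> Cohort:
    """Generate an annotated cohort; a fixed seed yields an identical one."""
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = GeneratorConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)
    grid = np.round(
        np.arange(0.0, config.t_total + config.sampling_dt / 2, config.sampling_dt), 9
    )
    probs = [
        config.p_sporulate,
        config.p_burst_only,
        config.p_transient_localization,
        config.p_quiescent,
    ]
    traces: list[CellTrace] = []
    truth_rows: list[tuple] = []
    width = max(3, len(str(max(config.n_cells - 1, 0))))
    for i in range(config.n_cells):
        cid = f"cell_{i:0{width}d}"
        fate = str(rng.choice(FATES, p=probs))
        if fate == "sporulating":
            tr, rows = _sporulating_cell(cid, grid, config, rng)
        elif fate == "burst_only":
            tr, rows = _burst_only_cell(cid, grid, config, rng)
        elif fate == "transient_localization":
            tr, rows = _transient_localization_cell(cid, grid, config, rng)
        else:
            tr, rows = _quiescent_cell(cid, grid, config, rng)
        tr.fate = fate
        traces.append(tr)
        truth_rows.extend((cid, fate, ev, t) for ev, t in rows)
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "fate", "event", "time_h"])
    return Cohort(traces=traces, truth=truth, config=config)


def _noise(rng, shape, config):
    return rng.normal(0.0, config.noise_sd, size=shape) if config.noise_sd else 0.0


def _baseline_channels(grid, config, rng, names=(CH_0A, CH_0F, CH_IIE, CH_IIR)):
    return {name: np.zeros_like(grid) + _noise(rng, grid.shape, config) for name in names}


def _sporulating_cell(cid, grid, config, rng):
    t0 = rng.uniform(*config.sporulation_start_window)
    amps = {name: rng.uniform(0.8, 1.2) for name in config.onset_offsets}
    onsets = {name: t0 + off for name, off in config.onset_offsets.items()}
    # commitment clock starts at the first noiseless grid crossing of the
    # activation threshold, so the measured interval carries the configured
    # distribution rather than an extra grid-quantization offset
    iir = _ramp(grid, onsets[CH_IIR], config.rise_tau[CH_IIR], amps[CH_IIR])
    cross_idx = np.flatnonzero(iir > config.activation_threshold * amps[CH_IIR])
    t_cross = float(grid[cross_idx[0]])
    interval = _lognormal(rng, config.commitment_median, config.commitment_cv)
    spore_time = t_cross + interval
    # observe through the frame in which the spore appears
    last = int(np.searchsorted(grid, spore_time - 1e-9))
    times = grid[: min(last + 1, grid.size)]
    spore_time = min(spore_time, float(times[-1]))

    channels = {}
    for name in config.onset_offsets:
        x = _ramp(times, onsets[name], config.rise_tau[name], amps[name])
        channels[name] = x + _noise(rng, times.shape, config)

    cycle = _lognormal(rng, config.cycle_median, config.cycle_cv)
    d0 = rng.uniform(0.2, 0.8)
    divisions: tuple[float, ...]
    if d0 + cycle > spore_time - 0.2:
        d0 = spore_time - 0.2 - cycle
    if d0 >= 0.05:
        divisions = (d0, d0 + cycle)
    else:  # cycle does not fit before the spore; no cycle measurable
        divisions = (rng.uniform(0.2, 0.8),)
    loc_interval = (onsets[CH_IIE], spore_time)
    trace = CellTrace(
        cell_id=cid,
        times=times,
        channels=channels,
        spore_time=spore_time,
        division_times=divisions,
        localization_intervals=(loc_interval,),
    )
    rows = [("activation", t_cross), ("spore", spore_time), ("commitment_interval_h", interval)]
    rows += [(f"onset_{name}", onsets[name]) for name in sorted(onsets)]
    rows += [("division", d) for d in divisions]
    if len(divisions) == 2:
        rows.append(("cycle_h", cycle))
    rows += [("localization_start", loc_interval[0]), ("localization_end", loc_interval[1])]
    return trace, rows


def _burst_slots(config, rng, t_total):
    """Burst start times: one per slot so excursions never overlap."""
    span = 3.5  # rise + decay back to baseline, with margin
    max_count = max(1, int((t_total - 2.0) / span))
    count = 1 + rng.poisson(config.burst_rate - 1.0)
    count = min(count, max_count)
    width = (t_total - 2.0) / count
    starts = [1.0 + k * width + rng.uniform(0.0, max(width - span, 0.0)) for k in range(count)]
    return starts


def _burst_only_cell(cid, grid, config, rng):
    starts = _burst_slots(config, rng, config.t_total)
    channels = _baseline_channels(grid, config, rng)
    for name in (CH_0A, CH_0F):
        for s in starts:
            amp = rng.uniform(*config.burst_amplitude)
            channels[name] = channels[name] + _pulse(
                grid, s, amp, config.burst_rise_tau,
                config.burst_rise_duration, config.burst_decay_tau,
            )
    trace = CellTrace(cell_id=cid, times=grid, channels=channels)
    rows = [("burst_start", s) for s in starts]
    return trace, rows


def _transient_localization_cell(cid, grid, config, rng):
    start = rng.uniform(1.0, config.t_total - 3.0)
    duration = rng.uniform(*config.localization_duration)
    channels = _baseline_channels(grid, config, rng)
    amp = rng.uniform(*config.burst_amplitude)
    channels[CH_IIE] = channels[CH_IIE] + _pulse(
        grid, start, amp, config.burst_rise_tau, duration, config.burst_decay_tau
    )
    trace = CellTrace(
        cell_id=cid,
        times=grid,
        channels=channels,
        localization_intervals=((start, start + duration),),
    )
    rows = [("localization_start", start), ("localization_end", start + duration)]
    return trace, rows


def _quiescent_cell(cid, grid, config, rng):
    return CellTrace(cell_id=cid, times=grid, channels=_baseline_channels(grid, config, rng)), []


# -- parameter recovery -------------------------------------------------------


def _bootstrap_ci(values: np.ndarray, stat, n_boot: int, rng, alpha=0.05):
    n = values.shape[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = stat(values[idx])
    return float(np.quantile(reps, alpha / 2)), float(np.quantile(reps, 1 - alpha / 2))


def recovery_report(
    cohort: Cohort,
    threshold_frac: float = 0.6,
    onset_threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare generator ground truth against trace-analysis estimates.

    One row per statistic with truth, estimate, error and a pass flag:
    commitment-interval CV and median-interval/median-cycle ratio (pass if
    the truth lies in the estimate's bootstrap 95% CI), transient-
    localization fraction and per-cell burst count (pass within 3 standard
    errors), and the ordering of mean channel onsets (pass if it matches
    the programmed temporal hierarchy).
    """
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    rows = []

    spor = [tr for tr in cohort.traces if tr.fate == "sporulating"]
    if spor:
        stats = commitment_intervals(cohort.traces, threshold_frac=threshold_frac)
        lo, hi = _bootstrap_ci(
            stats.intervals_h,
            lambda x: x.std(ddof=1) / x.mean() if x.std(ddof=1) > 0 else 0.0,
            n_boot,
            rng,
        )
        rows.append(
            ("commitment_cv", cfg.commitment_cv, stats.cv, stats.cv - cfg.commitment_cv,
             f"bootstrap 95% CI [{lo:.3f}, {hi:.3f}]", lo <= cfg.commitment_cv <= hi)
        )
        if stats.median_interval_over_median_cycle is not None:
            truth_ratio = 100.0 * cfg.commitment_median / cfg.cycle_median
            est_ratio = 100.0 * stats.median_interval_over_median_cycle
            # joint bootstrap: intervals and cycle durations both carry
            # sampling noise, so resample cells for the two medians together
            cycles = stats.cycle_durations_h
            pairs = np.column_stack([
                stats.intervals_h,
                np.concatenate([cycles, np.full(len(stats.intervals_h) - cycles.size, np.nan)]),
            ])
            lo, hi = _bootstrap_ci(
                pairs,
                lambda p: 100.0 * float(np.median(p[:, 0]) / np.nanmedian(p[:, 1])),
                n_boot,
                rng,
            )
            rows.append(
                ("median_interval_over_cycle_pct", truth_ratio, est_ratio,
                 est_ratio - truth_ratio, f"bootstrap 95% CI [{lo:.1f}, {hi:.1f}]",
                 lo <= truth_ratio <= hi)
            )

    frac, sem, n_transient, n = transient_localization_fraction(cohort.traces)
    tol = 3 * sem if sem > 0 else 3 * math.sqrt(
        cfg.p_transient_localization * (1 - cfg.p_transient_localization) / n
    )
    rows.append(
        ("transient_localization_fraction", cfg.p_transient_localization, frac,
         frac - cfg.p_transient_localization, f"3 SEM = {tol:.4f}",
         abs(frac - cfg.p_transient_localization) <= tol)
    )

    bursty = [tr for tr in cohort.traces if tr.fate == "burst_only"]
    if bursty:
        counts = np.array(
            [len(detect_bursts(tr, CH_0A)) for tr in bursty], dtype=float
        )
        est = float(counts.mean())
        se = float(counts.std(ddof=1) / math.sqrt(counts.size)) if counts.size > 1 else float("inf")
        rows.append(
            ("burst_count_per_cell", cfg.burst_rate, est, est - cfg.burst_rate,
             f"3 SE = {3 * se:.3f}", abs(est - cfg.burst_rate) <= 3 * se)
        )

    if spor:
        mean_onsets = {}
        for name in cfg.onset_offsets:
            onsets = [
                detect_activation(tr, name, onset_threshold)
                for tr in spor
                if name in tr.channels
            ]
            onsets = [t for t in onsets if t is not None]
            if onsets:
                mean_onsets[name] = float(np.mean(onsets))
        truth_order = " < ".join(sorted(cfg.onset_offsets, key=cfg.onset_offsets.get))
        est_order = " < ".join(sorted(mean_onsets, key=mean_onsets.get))
        rows.append(
            ("onset_ordering", truth_order, est_order, "", "exact ordering",
             truth_order == est_order)
        )

    return pd.DataFrame(
        rows, columns=["statistic", "truth", "estimate", "error", "tolerance", "passed"]
    )
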