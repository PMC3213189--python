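"""Single-cell reporter-trace analysis.

Operations mirror the measurements made on sporulation reporter movies:
amplitude normalization, fractional-of-maximum activation calling,
alignment of cohorts on a common reporter's activation, commitment-timing
statistics (interval between late-reporter activation and spore
appearance), hysteresis burst calling on early reporters, and the
fraction of cells with transient septal-localization events.

Traces live on a nominally regular sampling grid (20-minute frames in the
underlying movies) and carry optional event annotations: spore
appearance (the phase-bright spot), division times, and
septal-localization intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CH_0A",
    "CH_0F",
    "CH_IIE",
    "CH_IIR",
    "CellTrace",
    "Burst",
    "AlignedCohort",
    "CommitmentStats",
    "normalize_amplitude",
    "detect_activation",
    "align_and_average",
    "commitment_intervals",
    "detect_bursts",
    "transient_localization_fraction",
    "moving_average",
    "traces_to_frame",
    "annotations_to_frame",
    "traces_from_frames",
    "write_traces",
    "read_traces",
]

# Reporter channel names: promoter activities of spo0A, spo0F and spoIIR,
# and polar fluorescence of the SpoIIE translational fusion.
CH_0A = "Pspo0A"
CH_0F = "Pspo0F"
CH_IIE = "SpoIIE"
CH_IIR = "PspoIIR"


@dataclass
class CellTrace:
    """One cell's multi-channel fluorescence time series plus annotations.

    ``channels`` maps channel name to a fluorescence series (arbitrary
    units) with one value per timestamp.  ``spore_time`` is the phase-
    bright spore appearance; ``localization_intervals`` are (start, end)
    times of septal SpoIIE localization.
    """

    cell_id: str
    times: np.ndarray
    channels: dict[str, np.ndarray]
    spore_time: float | None = None
    division_times: tuple[float, ...] = ()
    localization_intervals: tuple[tuple[float, float], ...] = ()
    fate: str | None = None  # ground-truth label for synthetic cohorts

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace timestamps must be strictly increasing")
        for name, series in self.channels.items():
            series = np.asarray(series, dtype=float)
            self.channels[name] = series
            if series.shape != self.times.shape:
                raise ValueError(f"channel {name} length does not match timestamps")
        lo, hi = self.times[0], self.times[-1]
        eps = 1e-9
        for t in self._annotation_times():
            if not (lo - eps <= t <= hi + eps):
                raise ValueError(
                    f"annotation time {t} outside observed interval [{lo}, {hi}]"
                )

    def _annotation_times(self):
        if self.spore_time is not None:
            yield self.spore_time
        yield from self.division_times
        for a, b in self.localization_intervals:
            yield a
            yield b

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"cell {self.cell_id} has no channel {name!r}") from None


def normalize_amplitude(trace: CellTrace, channel: str) -> np.ndarray:
    """Min-max normalize a channel to [0, 1].

    Raises
    ------
    ValueError
        If the series is constant (normalization undefined).
    """
    x = trace.channel(channel)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError(
            f"channel {channel} of cell {trace.cell_id} is constant; "
            "amplitude normalization is undefined"
        )
    return (x - lo) / (hi - lo)


def detect_activation(
    trace: CellTrace, channel: str, threshold_frac: float = 0.7
) -> float | None:
    """First time the channel strictly exceeds ``threshold_frac`` of its
    maximum over the trace; ``None`` if it never does.

    The threshold is a fraction of the cell's own dynamic range above its
    baseline (minimum), so the call is invariant under positive affine
    rescaling of the fluorescence.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    x = trace.channel(channel)
    lo = x.min()
    above = x - lo > threshold_frac * (x.max() - lo)
    idx = np.flatnonzero(above)
    return float(trace.times[idx[0]]) if idx.size else None


@dataclass
class AlignedCohort:
    """Cohort mean +/- SD per channel on a common activation-relative grid."""

    rel_times: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    n_cells: np.ndarray  # cells contributing at each relative time
    n_aligned: int
    n_excluded: int  # cells without a reference activation

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"rel_time_h": self.rel_times, "n_cells": self.n_cells})
        for name in self.mean:
            df[f"{name}_mean"] = self.mean[name]
            df[f"{name}_sd"] = self.sd[name]
        return df


def align_and_average(
    traces: list[CellTrace],
    ref_channel: str = CH_IIR,
    threshold_frac: float = 0.7,
    channels: list[str] | None = None,
) -> AlignedCohort:
    """Align traces on reference-channel activation and average per channel.

    Each trace is shifted so its reference activation time is 0; channels
    are amplitude-normalized per cell, then the mean and sample SD are
    computed per relative timestamp over the cells observed there (ragged
    alignment).  Cells with no reference activation are excluded and
    counted in ``n_excluded``.
    """
    shifted: list[tuple[np.ndarray, CellTrace]] = []
    n_excluded = 0
    for tr in traces:
        t_act = detect_activation(tr, ref_channel, threshold_frac)
        if t_act is None:
            n_excluded += 1
            continue
        shifted.append((tr.times - t_act, tr))
    if not shifted:
        raise ValueError("no trace shows a reference-channel activation")
    if channels is None:
        channels = sorted(set().union(*(tr.channels for _, tr in shifted)))

    rel_times = np.unique(np.concatenate([t.round(9) for t, _ in shifted]))
    pos = {t: i for i, t in enumerate(rel_times)}
    n = rel_times.size
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    counts_any = np.zeros(n, dtype=int)
    for name in channels:
        s = np.zeros(n)
        s2 = np.zeros(n)
        cnt = np.zeros(n, dtype=int)
        for t, tr in shifted:
            if name not in tr.channels:
                continue
            x = normalize_amplitude(tr, name)
            idx = np.fromiter((pos[v] for v in t.round(9)), dtype=int, count=t.size)
            s[idx] += x
            s2[idx] += x * x
            cnt[idx] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
            var = np.where(
                cnt > 1, (s2 - cnt * mu * mu) / np.maximum(cnt - 1, 1), 0.0
            )
        mean[name] = mu
        sd[name] = np.sqrt(np.maximum(var, 0.0))
        counts_any = np.maximum(counts_any, cnt)
    return AlignedCohort(
        rel_times=rel_times,
        mean=mean,
        sd=sd,
        n_cells=counts_any,
        n_aligned=len(shifted),
        n_excluded=n_excluded,
    )


@dataclass
class CommitmentStats:
    """Distribution of the activation-to-spore interval, with the
    cell-cycle comparison measured in the same cells."""

    cell_ids: list[str]
    intervals_h: np.ndarray
    mean_h: float
    sd_h: float
    cv: float
    cycle_durations_h: np.ndarray
    median_interval_over_median_cycle: float | None
    n_excluded: int
    degenerate: bool = False  # single interval: CV is 0 by convention

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "interval_h": self.intervals_h})


def commitment_intervals(
    traces: list[CellTrace],
    threshold_frac: float = 0.6,
    ref_channel: str = CH_IIR,
) -> CommitmentStats:
    """Per-cell interval between late-reporter activation and spore
    appearance, its CV, and the ratio of median interval to median
    cell-cycle duration.

    Cells missing either the activation or the spore annotation are
    excluded and counted.  Cell-cycle durations are differences of
    consecutive division annotations of the same cells.
    """
    ids: list[str] = []
    intervals: list[float] = []
    cycles: list[float] = []
    n_excluded = 0
    for tr in traces:
        t_act = detect_activation(tr, ref_channel, threshold_frac)
        if t_act is None or tr.spore_time is None:
            n_excluded += 1
            continue
        dt = tr.spore_time - t_act
        if dt <= 0:
            n_excluded += 1
            continue
        ids.append(tr.cell_id)
        intervals.append(dt)
        if len(tr.division_times) >= 2:
            cycles.extend(np.diff(sorted(tr.division_times)).tolist())
    if not intervals:
        raise ValueError("no cell has both a reference activation and a spore")
    x = np.asarray(intervals)
    mean = float(x.mean())
    degenerate = x.size < 2
    sd = 0.0 if degenerate else float(x.std(ddof=1))
    cyc = np.asarray(cycles)
    ratio = float(np.median(x) / np.median(cyc)) if cyc.size else None
    return CommitmentStats(
        cell_ids=ids,
        intervals_h=x,
        mean_h=mean,
        sd_h=sd,
        cv=sd / mean,
        cycle_durations_h=cyc,
        median_interval_over_median_cycle=ratio,
        n_excluded=n_excluded,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class Burst:
    """A transient excursion of reporter activity: rise above the on
    threshold followed by a fall below the off threshold."""

    start_h: float
    peak_h: float
    end_h: float
    peak_value: float


def detect_bursts(
    trace: CellTrace,
    channel: str,
    theta_on: float = 0.5,
    theta_off: float = 0.2,
    require_uncommitted: bool = True,
    min_range: float = 0.0,
) -> list[Burst]:
    """Hysteresis burst calling on one channel.

    A burst is a maximal excursion that rises above ``theta_on`` and
    subsequently falls below ``theta_off``, both as fractions of the
    channel's dynamic range above its baseline; its start
    is the first above-``theta_off`` sample of the excursion and its end the
    first sub-``theta_off`` sample after it, so overlapping excursions
    merge.  An excursion still above the off threshold when the trace ends
    is not a burst (the cell commits rather than reverses).  Committed
    cells — those carrying a spore annotation, in which the late reporter
    was activated — return no bursts when ``require_uncommitted`` is set.

    Fractional thresholds carry no absolute scale, so a silent channel
    containing only measurement noise will show spurious "bursts" of its
    own noise floor; pass ``min_range`` (in fluorescence units) to require
    a minimum dynamic range before any burst is called.
    """
    if not 0 < theta_off < theta_on < 1:
        raise ValueError("thresholds must satisfy 0 < theta_off < theta_on < 1")
    if require_uncommitted and trace.spore_time is not None:
        return []
    x = trace.channel(channel)
    if x.max() - x.min() <= min_range:
        return []
    base = x.min()
    hi = base + theta_on * (x.max() - base)
    lo = base + theta_off * (x.max() - base)
    t = trace.times
    bursts: list[Burst] = []
    i = 0
    n = x.size
    while i < n:
        if x[i] > hi:
            j = i
            while j > 0 and x[j - 1] > lo:
                j -= 1
            k = i
            while k < n and x[k] > lo:
                k += 1
            if k < n:  # fell back below the off threshold: a real burst
                seg = slice(j, k + 1)
                peak = j + int(np.argmax(x[seg]))
                bursts.append(
                    Burst(
                        start_h=float(t[j]),
                        peak_h=float(t[peak]),
                        end_h=float(t[k]),
                        peak_value=float(x[peak]),
                    )
                )
                i = k + 1
            else:
                break
        else:
            i += 1
    return bursts


def transient_localization_fraction(
    traces: list[CellTrace],
) -> tuple[float, float, int, int]:
    """Fraction of cells with a septal-localization interval that ends
    without a subsequent spore, with its binomial SEM.

    Returns ``(fraction, sem, n_transient, n_cells)``.  A localization
    interval in a cell whose spore appears at or after the interval's end
    is part of a completed sporulation, not a transient event.
    """
    if not traces:
        raise ValueError("empty cohort")
    n = len(traces)
    n_transient = 0
    for tr in traces:
        transient = any(
            tr.spore_time is None or tr.spore_time < end - 1e-9
            for _, end in tr.localization_intervals
        )
        n_transient += bool(transient)
    p = n_transient / n
    sem = math.sqrt(p * (1 - p) / n)
    return p, sem, n_transient, n


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Optional centered moving average (edges use shorter windows)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(window)
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series, dtype=float), kernel, mode="same")
    return num / den


# -- tidy CSV dialects --------------------------------------------------------
# traces: cell_id, time_h, channel, value
# annotations: cell_id, event_type in {spore, division, localization_start,
#              localization_end}, time_h  (start/end pairs in time order)


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for name, series in sorted(tr.channels.items()):
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": tr.cell_id,
                        "time_h": tr.times,
                        "channel": name,
                        "value": series,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def annotations_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    rows: list[tuple[str, str, float]] = []
    for tr in traces:
        if tr.spore_time is not None:
            rows.append((tr.cell_id, "spore", tr.spore_time))
        for t in tr.division_times:
            rows.append((tr.cell_id, "division", t))
        for a, b in tr.localization_intervals:
            rows.append((tr.cell_id, "localization_start", a))
            rows.append((tr.cell_id, "localization_end", b))
    return pd.DataFrame(rows, columns=["cell_id", "event_type", "time_h"])


def traces_from_frames(
    trace_df: pd.DataFrame, ann_df: pd.DataFrame | None = None
) -> list[CellTrace]:
    ann_by_cell: dict[str, pd.DataFrame] = {}
    if ann_df is not None and len(ann_df):
        ann_by_cell = {str(cid): g for cid, g in ann_df.groupby("cell_id")}
    traces = []
    for cid, g in trace_df.groupby("cell_id", sort=True):
        cid = str(cid)
        wide = g.pivot_table(index="time_h", columns="channel", values="value", sort=True)
        times = wide.index.to_numpy(dtype=float)
        channels = {str(c): wide[c].to_numpy(dtype=float) for c in wide.columns}
        spore = None
        divisions: list[float] = []
        loc_starts: list[float] = []
        loc_ends: list[float] = []
        for _, row in ann_by_cell.get(cid, pd.DataFrame()).iterrows():
            kind, t = row["event_type"], float(row["time_h"])
            if kind == "spore":
                spore = t
            elif kind == "division":
                divisions.append(t)
            elif kind == "localization_start":
                loc_starts.append(t)
            elif kind == "localization_end":
                loc_ends.append(t)
            else:
                raise ValueError(f"unknown annotation event type {kind!r}")
        if len(loc_starts) != len(loc_ends):
            raise ValueError(f"unpaired localization interval for cell {cid}")
        intervals = tuple(zip(sorted(loc_starts), sorted(loc_ends)))
        traces.append(
            CellTrace(
                cell_id=cid,
                times=times,
                channels=channels,
                spore_time=spore,
                division_times=tuple(sorted(divisions)),
                localization_intervals=intervals,
            )
        )
    return traces


def write_traces(traces: list[CellTrace], trace_path, annotation_path=None) -> None:
    traces_to_frame(traces).to_csv(trace_path, index=False, float_format="%.9g")
    if annotation_path is not None:
        annotations_to_frame(traces).to_csv(
            annotation_path, index=False, float_format="%.9g"
        )


def read_traces(trace_path, annotation_path=None) -> list[CellTrace]:
    trace_df = pd.read_csv(trace_path)
    ann_df = pd.read_csv(annotation_path) if annotation_path is not None else None
    return traces_from_frames(trace_df, ann_df)
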