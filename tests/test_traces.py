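"""Single-cell trace operations: normalization, event calling, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sporedyn.traces import (
    CH_IIR,
    CellTrace,
    align_and_average,
    commitment_intervals,
    detect_activation,
    detect_bursts,
    moving_average,
    normalize_amplitude,
    read_traces,
    transient_localization_fraction,
    write_traces,
)


def trace(values, times=None, cell_id="c0", channel=CH_IIR, **kw):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    return CellTrace(cell_id=cell_id, times=times, channels={channel: values}, **kw)


def test_trace_invariants_enforced():
    with pytest.raises(ValueError):
        trace([1, 2, 3], times=np.array([0.0, 0.0, 1.0]))
    with pytest.raises(ValueError):
        CellTrace("c", np.array([0.0, 1.0]), {CH_IIR: np.array([1.0])})
    with pytest.raises(ValueError):
        trace([1, 2, 3], spore_time=9.0)


class TestNormalize:
    def test_basic(self):
        out = normalize_amplitude(trace([2, 4, 6]), CH_IIR)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        tr = trace([0.0, 0.25, 1.0])
        np.testing.assert_allclose(normalize_amplitude(tr, CH_IIR), tr.channels[CH_IIR])

    def test_preserves_argmax(self):
        x = np.array([0.1, 3.0, 2.0, 0.5])
        out = normalize_amplitude(trace(x), CH_IIR)
        assert np.argmax(out) == np.argmax(x)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_amplitude(trace([5, 5, 5]), CH_IIR)


class TestDetectActivation:
    def test_fractional_thresholds(self):
        tr = trace([0, 0, 70, 100])
        assert detect_activation(tr, CH_IIR, 0.7) == 3.0
        assert detect_activation(tr, CH_IIR, 0.6) == 2.0

    def test_never_exceeded_returns_none(self):
        # a flat series has zero dynamic range: nothing ever exceeds it
        assert detect_activation(trace([3, 3, 3]), CH_IIR, 0.7) is None
        assert detect_activation(trace([0, 0, 0.1, 0.2]), CH_IIR, 0.9) == 3.0

    def test_missing_channel_rejected(self):
        with pytest.raises(KeyError):
            detect_activation(trace([0, 1]), "Pspo0A")

    @given(scale=st.floats(0.01, 100.0), offset=st.floats(-50.0, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_positive_affine_rescaling(self, scale, offset):
        x = np.array([0.0, 0.1, 0.3, 0.8, 1.0, 0.9])
        t0 = detect_activation(trace(x), CH_IIR, 0.6)
        t1 = detect_activation(trace(scale * x + offset), CH_IIR, 0.6)
        assert t0 == t1

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_activation(trace([0, 1]), CH_IIR, 1.5)


class TestAlignAndAverage:
    def test_single_trace_mean_is_the_trace(self):
        tr = trace([0.0, 1.0, 4.0, 2.0])
        out = align_and_average([tr], CH_IIR, 0.7)
        np.testing.assert_allclose(out.mean[CH_IIR], normalize_amplitude(tr, CH_IIR))
        np.testing.assert_allclose(out.sd[CH_IIR], 0.0)
        assert out.n_aligned == 1 and out.n_excluded == 0

    def test_alignment_removes_a_pure_time_shift(self):
        x = np.array([0.0, 0.1, 0.5, 1.0, 1.0])
        t = np.arange(5, dtype=float)
        a = CellTrace("a", t, {CH_IIR: x})
        b = CellTrace("b", t + 1.0, {CH_IIR: x})
        out = align_and_average([a, b], CH_IIR, 0.7)
        overlap = out.n_cells == 2
        np.testing.assert_allclose(out.sd[CH_IIR][overlap], 0.0, atol=1e-12)

    def test_cells_without_activation_are_excluded_and_counted(self):
        good = trace([0, 0, 1, 2])
        flat_noise = trace([1.0, 0.4, 0.3, 0.2], cell_id="c1")
        out = align_and_average([good, flat_noise], CH_IIR, 0.7)
        # the declining trace's maximum is its first sample: activation at t=0
        assert out.n_aligned == 2
        with pytest.raises(ValueError):
            align_and_average([], CH_IIR, 0.7)


class TestCommitmentIntervals:
    def make_cohort(self, intervals, cycle=10.0):
        traces = []
        for i, dt in enumerate(intervals):
            t = np.arange(0.0, 20.0, 1.0)
            x = (t >= 5.0).astype(float)  # activation at 5 h
            traces.append(
                CellTrace(
                    f"c{i}", t, {CH_IIR: x},
                    spore_time=5.0 + dt,
                    division_times=(1.0, 1.0 + cycle),
                )
            )
        return traces

    def test_direct_arithmetic(self):
        stats = commitment_intervals(self.make_cohort([4.0, 5.0, 6.0]), 0.6)
        assert stats.mean_h == pytest.approx(5.0)
        assert stats.sd_h == pytest.approx(1.0)
        assert stats.cv == pytest.approx(0.2)
        assert stats.median_interval_over_median_cycle == pytest.approx(0.5)

    def test_single_interval_is_degenerate(self):
        stats = commitment_intervals(self.make_cohort([4.0]), 0.6)
        assert stats.degenerate and stats.cv == 0.0

    def test_cv_is_scale_invariant(self):
        a = commitment_intervals(self.make_cohort([2.0, 3.0, 4.0]), 0.6)
        b = commitment_intervals(self.make_cohort([6.0, 9.0, 12.0]), 0.6)
        assert a.cv == pytest.approx(b.cv)

    def test_no_usable_cells_rejected(self):
        tr = trace([0, 0, 1, 2])  # no spore annotation
        with pytest.raises(ValueError):
            commitment_intervals([tr], 0.6)


class TestDetectBursts:
    def test_monotone_ramp_is_not_a_burst(self):
        tr = trace([0.0, 0.2, 0.5, 0.9, 1.0])
        assert detect_bursts(tr, CH_IIR) == []

    def test_single_excursion(self):
        tr = trace([0.0, 0.9, 0.1, 0.0])
        bursts = detect_bursts(tr, CH_IIR)
        assert len(bursts) == 1
        b = bursts[0]
        assert b.start_h <= b.peak_h <= b.end_h
        assert b.peak_h == 1.0

    def test_two_separated_excursions(self):
        tr = trace([0.0, 1.0, 0.05, 0.0, 0.8, 0.05, 0.0])
        assert len(detect_bursts(tr, CH_IIR)) == 2

    def test_committed_cell_reports_no_bursts(self):
        tr = trace([0.0, 0.9, 0.1, 1.0], spore_time=3.0)
        assert detect_bursts(tr, CH_IIR) == []
        assert len(detect_bursts(tr, CH_IIR, require_uncommitted=False)) == 1

    def test_minimum_range_floor_silences_noise_channels(self):
        rng = np.random.default_rng(1)
        noise = trace(rng.normal(0.0, 0.05, size=50))
        assert detect_bursts(noise, CH_IIR, min_range=0.3) == []
        real = trace([0.0, 0.9, 0.05, 0.0])
        assert len(detect_bursts(real, CH_IIR, min_range=0.3)) == 1

    def test_invalid_threshold_ordering_rejected(self):
        tr = trace([0.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            detect_bursts(tr, CH_IIR, theta_on=0.2, theta_off=0.5)


class TestTransientLocalization:
    def cohort(self, n, transient_ids=(), sporulating_ids=()):
        traces = []
        for i in range(n):
            t = np.arange(0.0, 10.0, 1.0)
            kw = {}
            if i in transient_ids:
                kw["localization_intervals"] = ((2.0, 3.0),)
            if i in sporulating_ids:
                kw["localization_intervals"] = ((2.0, 5.0),)
                kw["spore_time"] = 5.0
            traces.append(CellTrace(f"c{i}", t, {CH_IIR: t * 1.0}, **kw))
        return traces

    def test_binomial_arithmetic(self):
        frac, sem, k, n = transient_localization_fraction(
            self.cohort(100, transient_ids=(0, 1))
        )
        assert frac == pytest.approx(0.02)
        assert sem == pytest.approx(np.sqrt(0.02 * 0.98 / 100))
        assert (k, n) == (2, 100)

    def test_no_events(self):
        frac, sem, k, n = transient_localization_fraction(self.cohort(10))
        assert frac == 0.0 and sem == 0.0

    def test_completed_sporulation_is_not_transient(self):
        frac, _, k, _ = transient_localization_fraction(
            self.cohort(10, sporulating_ids=(0, 1, 2))
        )
        assert k == 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            transient_localization_fraction([])


def test_moving_average_flat_preserved():
    x = np.ones(10)
    np.testing.assert_allclose(moving_average(x, 3), x)


def test_csv_round_trip(tmp_path):
    t = np.arange(0.0, 5.0, 1.0)
    traces = [
        CellTrace(
            "c0", t,
            {CH_IIR: np.array([0, 0, 1, 2, 3.0]), "Pspo0A": np.array([1, 2, 1, 0, 0.0])},
            spore_time=4.0,
            division_times=(1.0, 3.0),
            localization_intervals=((1.0, 2.0),),
        ),
        CellTrace("c1", t, {CH_IIR: np.array([0, 1, 0, 1, 0.0])}),
    ]
    tp, ap = tmp_path / "traces.csv", tmp_path / "ann.csv"
    write_traces(traces, tp, ap)
    back = read_traces(tp, ap)
    assert [tr.cell_id for tr in back] == ["c0", "c1"]
    np.testing.assert_allclose(back[0].channels[CH_IIR], traces[0].channels[CH_IIR])
    assert back[0].spore_time == 4.0
    assert back[0].division_times == (1.0, 3.0)
    assert back[0].localization_intervals == ((1.0, 2.0),)
    assert back[1].spore_time is None
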