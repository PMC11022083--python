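"""Segment integration, peaks, block statistics and percent change."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbkin import (
    Block,
    BlockStats,
    Event,
    SegmentSelection,
    analyze_segment,
    block_stats,
    event_peak,
    export_stats,
    peaks_by_block,
    percent_change,
)
from limbkin.conditioning import UncalibratedDataError
from limbkin.kinematics import SelectionError


def make_event(accel: np.ndarray, fs: float = 1000.0) -> Event:
    n = accel.shape[0]
    return Event(0, 0, np.arange(n), np.arange(n) / fs, accel)


def fine_grid_endpoint(a_of_t, T: float, fine_fs: float = 10000.0):
    """Independent oracle: trapezoid velocity/displacement at 10x sampling."""
    t = np.arange(int(round(T * fine_fs)) + 1) / fine_fs
    a = a_of_t(t)
    v = np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) / 2) / fine_fs])
    s = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2) / fine_fs])
    return v[-1], s[-1]


class TestAnalyzeSegment:
    def test_constant_acceleration_closed_form(self):
        # a = 2 m/s^2 for 1 s: v = aT = 2 m/s, s = aT^2/2 = 1 m
        n = 1001
        accel = np.zeros((n, 3))
        accel[:, 0] = 2.0
        sa = analyze_segment(make_event(accel), SegmentSelection(0, 0, 0, n), 1e-3)
        assert sa.velocity["x"].iloc[-1] == pytest.approx(2.0, abs=1e-3)
        assert sa.displacement["x"].iloc[-1] == pytest.approx(1.0, abs=1e-3)

    def test_zero_acceleration_stays_at_rest(self):
        sa = analyze_segment(
            make_event(np.zeros((100, 3))), SegmentSelection(0, 0, 0, 100), 1e-3
        )
        assert np.all(sa.velocity.to_numpy() == 0)
        assert np.all(sa.displacement.to_numpy() == 0)

    def test_sinusoid_closed_form(self):
        # a_x = sin(2 pi t): v_x(t) = (1 - cos(2 pi t)) / (2 pi),
        # so v at T = 1 is 0 and the peak velocity is 1/pi
        n = 1001
        t = np.arange(n) / 1000.0
        accel = np.zeros((n, 3))
        accel[:, 0] = np.sin(2 * np.pi * t)
        sa = analyze_segment(make_event(accel), SegmentSelection(0, 0, 0, n), 1e-3)
        assert sa.velocity["x"].iloc[-1] == pytest.approx(0.0, abs=2e-3)
        assert sa.velocity["x"].max() == pytest.approx(1 / np.pi, abs=1e-3)

    def test_linear_acceleration_exact_velocity(self):
        # trapezoid integrates degree-1 polynomials exactly
        n = 501
        t = np.arange(n) / 1000.0
        accel = np.zeros((n, 3))
        accel[:, 1] = 3.0 * t
        sa = analyze_segment(make_event(accel), SegmentSelection(0, 0, 0, n), 1e-3)
        assert sa.velocity["y"].iloc[-1] == pytest.approx(1.5 * t[-1] ** 2, rel=1e-12)

    def test_smooth_signal_matches_fine_grid_oracle(self):
        # O(dt^2) agreement with an independent 10x-sampled trapezoid
        f = lambda t: np.exp(-t) * np.cos(3 * t) * 4.0
        n = 1001
        t = np.arange(n) / 1000.0
        accel = np.zeros((n, 3))
        accel[:, 2] = f(t)
        sa = analyze_segment(make_event(accel), SegmentSelection(0, 0, 0, n), 1e-3)
        v_ref, s_ref = fine_grid_endpoint(f, 1.0)
        dt2 = 1e-3**2
        assert abs(sa.velocity["z"].iloc[-1] - v_ref) < 100 * dt2
        assert abs(sa.displacement["z"].iloc[-1] - s_ref) < 100 * dt2

    def test_series_start_at_rest_and_lengths_match(self, rng):
        accel = rng.normal(size=(64, 3))
        sa = analyze_segment(make_event(accel), SegmentSelection(0, 0, 10, 50), 1e-3)
        for df in (sa.acceleration, sa.velocity, sa.displacement):
            assert len(df) == 40
        assert np.all(sa.velocity.iloc[0][["x", "y", "z"]] == 0)
        assert np.all(sa.displacement.iloc[0][["x", "y", "z"]] == 0)
        assert len(sa.summary) == 12  # 3 quantities x 4 components

    def test_empty_or_invalid_selection_rejected(self):
        ev = make_event(np.zeros((10, 3)))
        with pytest.raises(SelectionError):
            analyze_segment(ev, SegmentSelection(0, 0, 5, 5), 1e-3)
        with pytest.raises(SelectionError):
            analyze_segment(ev, SegmentSelection(0, 0, 0, 11), 1e-3)


class TestEventPeak:
    def test_peak_of_magnitude_channel(self):
        accel = np.array([[0.1, 0, 0], [0, 3.2, 0], [0, 0, 1.0]])
        assert event_peak(make_event(accel)) == pytest.approx(3.2)

    def test_all_zero_event_peaks_at_zero(self):
        assert event_peak(make_event(np.zeros((10, 3)))) == 0.0

    def test_axis_component_peak(self):
        accel = np.array([[1.0, -5.0, 0.0], [2.0, -1.0, 0.0]])
        assert event_peak(make_event(accel), "x") == 2.0
        assert event_peak(make_event(accel), "y") == -1.0  # signed maximum

    def test_empty_event_rejected(self):
        ev = Event(0, 0, np.arange(0), np.arange(0.0), np.zeros((0, 3)))
        with pytest.raises(SelectionError):
            event_peak(ev)

    @settings(max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_abs_peak_dominates_axis_peaks(self, seed):
        accel = np.random.default_rng(seed).normal(size=(50, 3))
        ev = make_event(accel)
        for comp in ("x", "y", "z"):
            assert event_peak(ev, "abs") >= event_peak(ev, comp)


class TestBlockStats:
    def test_mean_and_sample_sd(self):
        peaks = [1.0, 2.0, 3.0]
        events = [make_event(np.array([[p, 0.0, 0.0]])) for p in peaks]
        stats = block_stats(Block(0, events))
        assert stats.mean_peak == pytest.approx(2.0)
        assert stats.sd_peak == pytest.approx(1.0)  # n-1 convention

    def test_single_event_sd_absent(self):
        stats = block_stats(Block(0, [make_event(np.array([[4.0, 0, 0]]))]))
        assert stats.mean_peak == pytest.approx(4.0)
        assert stats.sd_peak is None

    def test_sampling_distribution_of_mean(self):
        # 30 iid peaks from N(3, 0.2^2): block mean within 4 SE of 3
        rng = np.random.default_rng(42)
        peaks = rng.normal(3.0, 0.2, size=30)
        events = [make_event(np.array([[p, 0.0, 0.0]])) for p in peaks]
        stats = block_stats(Block(0, events))
        assert abs(stats.mean_peak - 3.0) < 4 * 0.2 / np.sqrt(30)


class TestPercentChange:
    def _stats(self, mean):
        return BlockStats(0, [mean], mean, None)

    @pytest.mark.parametrize(
        "first, last, expected",
        [(2.00, 3.05, 52.5), (2.0, 2.0, 0.0), (2.00, 1.748, -12.6)],
    )
    def test_arithmetic(self, first, last, expected):
        assert percent_change(self._stats(first), self._stats(last)) == pytest.approx(
            expected
        )

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percent_change(self._stats(0.0), self._stats(1.0))

    @settings(max_examples=30)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        first=st.floats(min_value=0.1, max_value=50),
        last=st.floats(min_value=0.1, max_value=50),
    )
    def test_invariant_under_common_rescaling(self, scale, first, last):
        base = percent_change(self._stats(first), self._stats(last))
        scaled = percent_change(self._stats(first * scale), self._stats(last * scale))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestPipelineGuard:
    def test_peaks_refused_on_uncalibrated_recording(self, random_recording):
        with pytest.raises(UncalibratedDataError):
            peaks_by_block(random_recording)
        # force flag overrides the guard
        stats = peaks_by_block(random_recording, force=True)
        assert len(stats) == random_recording.n_blocks


class TestExportStats:
    def _make_stats(self, n_blocks):
        rng = np.random.default_rng(0)
        out = []
        for b in range(n_blocks):
            peaks = rng.uniform(2, 6, size=5).tolist()
            arr = np.asarray(peaks)
            out.append(BlockStats(b, peaks, float(arr.mean()), float(arr.std(ddof=1))))
        return out

    def test_six_blocks_six_summary_rows(self, tmp_path):
        summary, events = export_stats(self._make_stats(6), tmp_path / "stats.tsv")
        df = pd.read_csv(summary, sep="\t")
        assert len(df) == 6
        edf = pd.read_csv(events, sep="\t")
        assert len(edf) == 30

    def test_empty_list_header_only(self, tmp_path):
        summary, events = export_stats([], tmp_path / "stats.tsv")
        assert pd.read_csv(summary, sep="\t").empty
        assert pd.read_csv(events, sep="\t").empty

    def test_round_trip_values_to_six_decimals(self, tmp_path):
        stats = self._make_stats(3)
        summary, _ = export_stats(stats, tmp_path / "stats.tsv")
        df = pd.read_csv(summary, sep="\t")
        for s, (_, row) in zip(stats, df.iterrows()):
            assert row["mean_peak"] == pytest.approx(s.mean_peak, abs=5e-7)
            assert row["sd_peak"] == pytest.approx(s.sd_peak, abs=5e-7)
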