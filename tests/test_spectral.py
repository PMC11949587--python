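"""Tests for band-pass filtering, phase extraction, PLI, thresholding and peaks."""

import numpy as np
import pytest

from conftest import random_pli
from hopfnet.errors import (
    DegenerateSignalError,
    FormatError,
    ValidationError,
)
from hopfnet.model import TimeSeriesPanel
from hopfnet.spectral import (
    PhasePanel,
    PLIMatrix,
    SpectralPeakTable,
    bandpass,
    epoch_average_pli,
    instantaneous_phase,
    median_peak_frequencies,
    median_threshold_pli,
    peak_frequency,
    phase_lag_index,
    pli_from_timeseries,
    read_pli,
    threshold_pli,
    trim_edges,
    write_pli,
)


def sine_panel(freqs_hz, fs=1250.0, duration=4.0, phases=None, labels=None):
    """Panel of pure sinusoids, one channel per frequency."""
    t = np.arange(int(duration * fs)) / fs
    freqs_hz = np.atleast_1d(freqs_hz)
    if phases is None:
        phases = np.zeros(len(freqs_hz))
    vals = np.stack(
        [np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs_hz, phases)], axis=1
    )
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(len(freqs_hz)))
    return TimeSeriesPanel(values=vals, fs_hz=fs, labels=labels)


def wrap(d):
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - d, 2 * np.pi)


class TestBandpass:
    def test_passband_preserved_stopband_removed(self):
        ts = sine_panel([10.0, 2.0, 40.0])
        out = bandpass(ts, 8.0, 12.0)
        mid = slice(1250, -1250)  # compare away from filter edges
        rms_in = np.sqrt(np.mean(ts.values[mid] ** 2, axis=0))
        rms_out = np.sqrt(np.mean(out.values[mid] ** 2, axis=0))
        assert rms_out[0] > 0.95 * rms_in[0]  # 10 Hz passes
        assert rms_out[1] < 0.05 * rms_in[1]  # 2 Hz blocked
        assert rms_out[2] < 0.05 * rms_in[2]  # 40 Hz blocked

    def test_zero_phase_no_lag_on_passband_tone(self):
        # filtfilt must not shift a passband tone: cross-correlate at lag 0
        ts = sine_panel([10.0])
        out = bandpass(ts, 8.0, 12.0)
        mid = slice(1250, -1250)
        a, b = ts.values[mid, 0], out.values[mid, 0]
        corr = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert corr > 0.999

    def test_invalid_band_rejected(self):
        ts = sine_panel([10.0])
        with pytest.raises(ValidationError):
            bandpass(ts, 12.0, 8.0)
        with pytest.raises(ValidationError):
            bandpass(ts, 8.0, 700.0)  # above Nyquist at 1250 Hz
        with pytest.raises(ValidationError):
            bandpass(ts, 0.0, 12.0)

    def test_linearity(self):
        ts1 = sine_panel([9.0])
        ts2 = sine_panel([11.0])
        both = TimeSeriesPanel(values=ts1.values + ts2.values, fs_hz=1250.0,
                               labels=("ch0",))
        out_sum = bandpass(both, 8.0, 12.0).values
        sum_out = bandpass(ts1, 8.0, 12.0).values + bandpass(ts2, 8.0, 12.0).values
        np.testing.assert_allclose(out_sum, sum_out, atol=1e-10)


class TestTrimAndPhase:
    def test_trim_lengths(self):
        ts = sine_panel([10.0], fs=250.0, duration=4.0)  # 1000 samples
        out = trim_edges(ts, 0.5)
        assert out.n_samples == 1000 - 2 * 125
        np.testing.assert_array_equal(out.values, ts.values[125:-125])

    def test_trim_whole_signal_rejected(self):
        ts = sine_panel([10.0], fs=250.0, duration=1.0)
        with pytest.raises(ValidationError):
            trim_edges(ts, 0.5)

    def test_trim_zero_is_identity(self):
        ts = sine_panel([10.0], fs=250.0, duration=2.0)
        assert trim_edges(ts, 0.0) is ts

    def test_phase_slope_matches_frequency(self):
        f = 10.0
        ts = sine_panel([f], fs=1250.0, duration=4.0)
        ph = instantaneous_phase(trim_edges(ts, 0.5)).phases[:, 0]
        dphi = wrap(np.diff(ph))
        est_f = np.median(dphi) * ts.fs_hz / (2 * np.pi)
        assert abs(est_f - f) < 0.01

    def test_phase_lag_recovered(self):
        lag = np.pi / 3
        ts = sine_panel([10.0, 10.0], phases=[0.0, -lag])
        ph = instantaneous_phase(trim_edges(ts, 0.5)).phases
        d = wrap(ph[:, 0] - ph[:, 1])
        np.testing.assert_allclose(np.median(d), lag, atol=1e-3)

    def test_zero_channel_degenerate(self):
        vals = np.zeros((500, 2))
        vals[:, 0] = np.sin(2 * np.pi * 10 * np.arange(500) / 250.0)
        ts = TimeSeriesPanel(values=vals, fs_hz=250.0, labels=("a", "b"))
        with pytest.raises(DegenerateSignalError):
            instantaneous_phase(ts)

    def test_too_short_rejected(self):
        ts = TimeSeriesPanel(values=np.ones((10, 1)), fs_hz=250.0, labels=("a",))
        with pytest.raises(ValidationError):
            instantaneous_phase(ts)

    def test_phase_panel_wrap_validated(self):
        with pytest.raises(ValidationError):
            PhasePanel(phases=np.full((10, 1), 4.0), fs_hz=250.0, labels=("a",))


def pli_of_phases(ph, labels=None):
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(ph.shape[1]))
    return phase_lag_index(PhasePanel(phases=ph, fs_hz=1250.0, labels=labels))


class TestPLI:
    def test_constant_quarter_pi_lag_is_one(self):
        t = np.arange(1000) / 1250.0
        base = wrap(2 * np.pi * 10.0 * t)
        ph = np.stack([base, wrap(base - np.pi / 4)], axis=1)
        pli = pli_of_phases(ph)
        assert pli.values[0, 1] == 1.0

    def test_identical_phases_is_zero(self):
        t = np.arange(1000) / 1250.0
        base = wrap(2 * np.pi * 10.0 * t)
        ph = np.stack([base, base], axis=1)
        pli = pli_of_phases(ph)
        assert pli.values[0, 1] == 0.0

    def test_antiphase_is_zero(self):
        # sin(pi) = 0 contributes sign 0, like identical phases; constant
        # phases keep the difference exactly pi (wrapping a moving phase
        # would leave pi +- 1 ulp and flip the sign sample by sample)
        ph = np.stack([np.zeros(1000), np.full(1000, np.pi)], axis=1)
        assert pli_of_phases(ph).values[0, 1] == 0.0

    def test_mixed_signs_half(self):
        # diffs (+a, +a, -a, +a): mean sign = 1/2
        a = 0.3
        d = np.array([a, a, -a, a])
        ph = np.stack([d, np.zeros(4)], axis=1)
        assert pli_of_phases(ph).values[0, 1] == pytest.approx(0.5)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        ph = wrap(rng.uniform(-4, 4, size=(200, 5)))
        got = pli_of_phases(ph).values
        # naive oracle straight from the definition
        T, N = ph.shape
        want = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                if i != j:
                    s = np.sign(np.sin(ph[:, i] - ph[:, j]))
                    want[i, j] = abs(np.mean(s))
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_symmetric_and_swap_invariant(self):
        rng = np.random.default_rng(1)
        ph = wrap(rng.uniform(-3, 3, size=(150, 4)))
        v = pli_of_phases(ph).values
        np.testing.assert_array_equal(v, v.T)
        v_sw = pli_of_phases(ph[:, ::-1]).values
        np.testing.assert_allclose(v_sw, v[::-1, ::-1], atol=1e-12)

    def test_global_phase_offset_invariance(self):
        rng = np.random.default_rng(2)
        ph = wrap(rng.uniform(-3, 3, size=(150, 3)))
        v = pli_of_phases(ph).values
        v_off = pli_of_phases(wrap(ph + 1.234)).values
        np.testing.assert_allclose(v_off, v, atol=1e-12)

    def test_pipeline_lagged_sines(self):
        # full pipeline on 10 Hz tones with a consistent lag -> PLI ~ 1
        ts = sine_panel([10.0, 10.0], phases=[0.0, -np.pi / 4], duration=4.0)
        pli = pli_from_timeseries(ts)
        assert pli.values[0, 1] > 0.99
        assert pli.source == "simulated"

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValidationError):
            PLIMatrix(values=np.array([[0.0, 1.5], [1.5, 0.0]]), labels=("a", "b"))
        with pytest.raises(ValidationError):
            PLIMatrix(values=np.array([[0.0, 0.2], [0.3, 0.0]]), labels=("a", "b"))
        with pytest.raises(ValidationError):
            PLIMatrix(values=np.array([[0.1, 0.2], [0.2, 0.0]]), labels=("a", "b"))


class TestEpochAverage:
    def test_mean_of_epochs(self):
        plis = [random_pli(5, s) for s in (1, 2, 3)]
        avg = epoch_average_pli(plis)
        want = np.mean([p.values for p in plis], axis=0)
        np.testing.assert_allclose(avg.values, want)
        assert avg.source == plis[0].source

    def test_rejects_thresholded_input(self):
        p = threshold_pli(random_pli(5, 4), 20.0)
        with pytest.raises(ValidationError):
            epoch_average_pli([p])

    def test_rejects_mismatched_labels(self):
        a = random_pli(4, 1)
        b = random_pli(4, 2, labels=("w", "x", "y", "z"))
        with pytest.raises(ValidationError):
            epoch_average_pli([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            epoch_average_pli([])


class TestThreshold:
    def test_zeroed_count_exact(self):
        p = random_pli(8, 5)  # 28 pairs
        for pct, n_zero in [(0.0, 0), (25.0, 7), (50.0, 14), (99.0, 27)]:
            out = threshold_pli(p, pct)
            n_zeroed = int(np.sum(out.upper_triangle() == 0.0))
            assert n_zeroed == n_zero
            assert out.threshold_applied == ("percentile", pct)

    def test_keeps_largest_pairs(self):
        # sort-and-cut oracle: surviving entries are exactly the top pairs
        p = random_pli(7, 6)  # 21 pairs, generic values (no ties)
        out = threshold_pli(p, 40.0)  # floor(21*0.4) = 8 zeroed
        upper = p.upper_triangle()
        cutoff = np.sort(upper)[8]
        iu = np.triu_indices(7, k=1)
        survived = out.values[iu] != 0.0
        np.testing.assert_array_equal(survived, upper >= cutoff)
        np.testing.assert_array_equal(out.values[iu][survived], upper[survived])

    def test_tie_break_by_row_then_col(self):
        # all entries equal: the first pairs in (row, col) order are zeroed
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0.0)
        p = PLIMatrix(values=v, labels=("a", "b", "c", "d"))
        out = threshold_pli(p, 50.0)  # floor(6*0.5) = 3 zeroed
        # (row, col) order: (0,1), (0,2), (0,3), (1,2), (1,3), (2,3)
        assert out.values[0, 1] == out.values[0, 2] == out.values[0, 3] == 0.0
        assert out.values[1, 2] == out.values[1, 3] == out.values[2, 3] == 0.5

    def test_monotone_in_percent(self):
        p = random_pli(8, 7)
        zeros = [
            int(np.sum(threshold_pli(p, pct).upper_triangle() == 0.0))
            for pct in (0, 10, 30, 60, 90)
        ]
        assert zeros == sorted(zeros)

    def test_double_threshold_rejected(self):
        out = threshold_pli(random_pli(5, 8), 20.0)
        with pytest.raises(ValidationError):
            threshold_pli(out, 20.0)

    def test_hundred_percent_rejected(self):
        with pytest.raises(ValidationError):
            threshold_pli(random_pli(5, 9), 100.0)
        with pytest.raises(ValidationError):
            threshold_pli(random_pli(5, 9), -1.0)

    def test_symmetry_preserved(self):
        out = threshold_pli(random_pli(6, 10), 50.0)
        np.testing.assert_array_equal(out.values, out.values.T)


class TestMedianThreshold:
    def test_strictly_below_median_zeroed(self):
        p = random_pli(6, 11)
        out = median_threshold_pli(p)
        med = np.median(p.upper_triangle())
        iu = np.triu_indices(6, k=1)
        want = np.where(p.values[iu] < med, 0.0, p.values[iu])
        np.testing.assert_array_equal(out.values[iu], want)
        assert out.threshold_applied == ("median", med)

    def test_entries_at_median_survive(self):
        v = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        v[iu] = [0.1, 0.2, 0.3, 0.3, 0.4, 0.5]  # median 0.3
        v = v + v.T
        p = PLIMatrix(values=v, labels=("a", "b", "c", "d"))
        out = median_threshold_pli(p)
        assert int(np.sum(out.upper_triangle() == 0.0)) == 2  # only 0.1 and 0.2

    def test_double_threshold_rejected(self):
        out = median_threshold_pli(random_pli(5, 12))
        with pytest.raises(ValidationError):
            median_threshold_pli(out)


class TestPeakFrequency:
    def test_tone_detected_flat_comb_rejected(self):
        rng = np.random.default_rng(0)
        fs, dur = 1250.0, 13.5
        t = np.arange(int(fs * dur)) / fs
        # flat-spectrum comb: equal-power tones on every 0.5 Hz Welch bin in
        # 4.5-48 Hz, so peak density ~ background mean and the 2x rule rejects
        comb_freqs = np.arange(4.5, 48.0, 0.5)
        comb = sum(
            np.sin(2 * np.pi * f * t + p)
            for f, p in zip(comb_freqs, rng.uniform(0, 2 * np.pi, comb_freqs.size))
        )
        vals = np.stack(
            [np.sin(2 * np.pi * 10.0 * t) + 0.1 * rng.normal(size=t.size), comb],
            axis=1,
        )
        ts = TimeSeriesPanel(values=vals, fs_hz=fs, labels=("tone", "comb"))
        table = peak_frequency(ts)
        assert table.accepted[0]
        assert abs(table.peak_hz[0] - 10.0) <= 0.5  # Welch resolution
        assert not table.accepted[1]
        assert np.isnan(table.peak_hz[1])

    def test_low_frequency_peak_ignored(self):
        # dominant 2 Hz tone is below the 4 Hz floor; a weaker 10 Hz tone wins
        fs = 1250.0
        t = np.arange(int(fs * 10.0)) / fs
        vals = (3.0 * np.sin(2 * np.pi * 2.0 * t)
                + np.sin(2 * np.pi * 10.0 * t))[:, None]
        ts = TimeSeriesPanel(values=vals, fs_hz=fs, labels=("a",))
        table = peak_frequency(ts)
        assert table.accepted[0]
        assert abs(table.peak_hz[0] - 10.0) <= 0.5

    def test_too_short_rejected(self):
        ts = sine_panel([10.0], fs=250.0, duration=1.5)
        with pytest.raises(ValidationError):
            peak_frequency(ts)

    def test_table_invariant(self):
        with pytest.raises(ValidationError):
            SpectralPeakTable(labels=("a",), peak_hz=np.array([3.0]),
                              accepted=np.array([True]))


class TestMedianPeaks:
    def _table(self, peaks, accepted, labels):
        return SpectralPeakTable(labels=labels, peak_hz=np.asarray(peaks, float),
                                 accepted=np.asarray(accepted, bool))

    def test_per_region_median(self):
        labels = ("a", "b")
        tables = [
            self._table([9.0, 11.0], [True, True], labels),
            self._table([10.0, 10.0], [True, True], labels),
            self._table([11.0, 9.0], [True, True], labels),
        ]
        np.testing.assert_allclose(median_peak_frequencies(tables), [10.0, 10.0])

    def test_rejected_peaks_excluded(self):
        labels = ("a",)
        tables = [
            self._table([9.0], [True], labels),
            self._table([40.0], [False], labels),  # rejected: must not count
            self._table([11.0], [True], labels),
        ]
        np.testing.assert_allclose(median_peak_frequencies(tables), [10.0])

    def test_fallback_to_global_median(self, caplog):
        labels = ("a", "b", "c")
        tables = [self._table([9.0, 11.0, np.nan], [True, True, False], labels)]
        with caplog.at_level("WARNING"):
            med = median_peak_frequencies(tables)
        np.testing.assert_allclose(med, [9.0, 11.0, 10.0])
        assert any("no accepted peak" in r.message for r in caplog.records)

    def test_no_peaks_anywhere_degenerate(self):
        labels = ("a",)
        tables = [self._table([np.nan], [False], labels)]
        with pytest.raises(DegenerateSignalError):
            median_peak_frequencies(tables)


class TestPLIIO:
    def test_roundtrip_bit_identical(self, tmp_path):
        p = threshold_pli(random_pli(10, 13), 30.0)
        write_pli(p, tmp_path / "p.csv")
        back = read_pli(tmp_path / "p.csv", labels=p.labels)
        np.testing.assert_array_equal(back.values, p.values)
        assert back.labels == p.labels
        assert back.source == p.source
        assert back.threshold_applied == p.threshold_applied

    def test_label_mismatch_rejected(self, tmp_path):
        p = random_pli(4, 14)
        write_pli(p, tmp_path / "p.csv")
        with pytest.raises(FormatError):
            read_pli(tmp_path / "p.csv", labels=("w", "x", "y", "z"))

    def test_missing_sidecar_defaults(self, tmp_path):
        p = random_pli(4, 15)
        write_pli(p, tmp_path / "p.csv")
        (tmp_path / "p.csv.json").unlink()
        back = read_pli(tmp_path / "p.csv")
        assert back.source == "empirical"
        assert back.threshold_applied is None
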