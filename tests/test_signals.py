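import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from ppgresp import (EventSeries, TimeSeries, artifact_reduce, bandpass,
                     normalize_range, read_series, segment_signal, write_series)
from conftest import sine_ts


class TestSegmentation:
    @pytest.mark.parametrize(
        "T,M,K,starts",
        [
            (100, 100, 50, [0]),                # single-window case
            (10, 4, 2, [0, 2, 4, 6]),           # S = floor((T-M)/K)+1 = 4
            (12, 4, 4, [0, 4, 8]),              # K = M tiles without overlap
        ],
    )
    def test_window_layout(self, T, M, K, starts):
        ts = TimeSeries(np.arange(T, dtype=float), fs=1.0)
        wins = segment_signal(ts, M, K)
        assert [w.start for w in wins] == starts
        for w in wins:
            assert len(w) == M
            np.testing.assert_array_equal(w.values, ts.values[w.start:w.start + M])

    def test_adjacent_overlap(self):
        ts = TimeSeries(np.random.default_rng(0).normal(size=50), fs=5.0)
        wins = segment_signal(ts, 20, 5)
        for a, b in zip(wins, wins[1:]):
            np.testing.assert_array_equal(a.values[5:], b.values[:15])

    def test_tiling_reconstructs_signal(self):
        # K = M: concatenated windows give back the first S*M samples
        ts = TimeSeries(np.random.default_rng(1).normal(size=103), fs=10.0)
        wins = segment_signal(ts, 20, 20)
        cat = np.concatenate([w.values for w in wins])
        np.testing.assert_array_equal(cat, ts.values[:100])

    def test_errors(self):
        ts = TimeSeries(np.zeros(10), fs=1.0)
        with pytest.raises(ValueError, match="longer than signal"):
            segment_signal(ts, 11, 1)
        with pytest.raises(ValueError, match="shift"):
            segment_signal(ts, 5, 0)


class TestBandpass:
    def test_passband_centre_preserved(self):
        ts = sine_ts(0.5, duration=120, fs=25)
        out = bandpass(ts, 0.18, 1.0, order=4)
        mid = slice(len(ts) // 4, -len(ts) // 4)
        ratio = np.std(out.values[mid]) / np.std(ts.values[mid])
        assert abs(ratio - 1) < 0.05

    def test_stopband_attenuation(self):
        # the designed 4th-order filter response at 0.05 Hz is down > 20 dB
        sos = butter(4, [0.18, 1.0], btype="bandpass", fs=25.0, output="sos")
        w, h = sosfreqz(sos, worN=[2 * np.pi * 0.05 / 25.0])
        assert 20 * np.log10(abs(h[0])) < -20

    def test_zero_in_zero_out(self):
        ts = TimeSeries(np.zeros(500), fs=25.0)
        out = bandpass(ts, 0.18, 1.0, order=4)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_inband_idempotence(self):
        ts = sine_ts(0.4, duration=120, fs=25)
        once = bandpass(ts, 0.18, 1.0, order=4)
        twice = bandpass(once, 0.18, 1.0, order=4)
        mid = slice(len(ts) // 4, -len(ts) // 4)
        assert abs(np.std(twice.values[mid]) / np.std(once.values[mid]) - 1) < 0.05

    def test_invalid_band(self):
        ts = sine_ts(0.5, duration=10, fs=25)
        with pytest.raises(ValueError, match="band"):
            bandpass(ts, 0.5, 20.0, order=4)
        with pytest.raises(ValueError, match="band"):
            bandpass(ts, 1.0, 0.5, order=4)


class TestNormalize:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0, 5, 10], [-1, 0, 1]),
            ([-2, 0, 2], [-1, 0, 1]),
            ([1, 2, 4], [-1, -1 / 3, 1]),
        ],
    )
    def test_affine_map(self, values, expected):
        out = normalize_range(TimeSeries(values, fs=1.0))
        np.testing.assert_allclose(out.values, expected)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_range(TimeSeries(np.ones(5), fs=1.0))


class TestArtifactReduce:
    def test_constant_gives_zero_derivative(self):
        ev = EventSeries(np.arange(10.0), np.full(10, 3.0))
        out = artifact_reduce(ev, out_fs=8.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_linear_ramp_gives_slope(self):
        ev = EventSeries(np.arange(10.0), 2.5 * np.arange(10.0) + 1)
        out = artifact_reduce(ev, out_fs=8.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-8)

    def test_sinusoid_derivative(self):
        f = 0.25
        t = np.arange(0, 40, 0.2)  # 20 points per cycle
        ev = EventSeries(t, np.sin(2 * np.pi * f * t))
        out = artifact_reduce(ev, out_fs=8.0)
        grid = np.arange(t[0], t[-1], 1 / 8.0)
        expect = 2 * np.pi * f * np.cos(2 * np.pi * f * grid)
        interior = slice(8, -8)
        err = np.sqrt(np.mean((out.values[interior] - expect[interior]) ** 2))
        assert err < 0.02 * np.sqrt(np.mean(expect[interior] ** 2))

    def test_linearity(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 10, 20))
        x, y = rng.normal(size=20), rng.normal(size=20)
        pa = artifact_reduce(EventSeries(t, x), out_fs=8.0)
        pb = artifact_reduce(EventSeries(t, y), out_fs=8.0)
        pab = artifact_reduce(EventSeries(t, 2 * x - 3 * y), out_fs=8.0)
        np.testing.assert_allclose(pab.values, 2 * pa.values - 3 * pb.values, atol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="insufficient"):
            artifact_reduce(EventSeries([0.0, 1, 2], [1.0, 2, 3]))


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        ts = sine_ts(0.3, duration=4, fs=25, label="x")
        path = tmp_path / "s.csv"
        write_series(ts, path)
        back = read_series(path)
        np.testing.assert_allclose(back.values, ts.values, atol=1e-9)
        assert abs(back.fs - ts.fs) < 1e-6
        # header line present and skipped
        assert open(path).readline().startswith("time_s")

    def test_npz_roundtrip(self, tmp_path):
        ts = sine_ts(0.3, duration=4, fs=25, label="lab")
        path = tmp_path / "s.npz"
        write_series(ts, path)
        back = read_series(path)
        np.testing.assert_array_equal(back.values, ts.values)
        assert back.fs == ts.fs and back.label == "lab"

    def test_jittered_time_column_rejected(self, tmp_path):
        rng = np.random.default_rng(0)
        t = np.arange(0, 4, 0.04) + rng.uniform(-0.002, 0.002, 100)
        t = np.sort(t)
        path = tmp_path / "bad.csv"
        with open(path, "w") as fh:
            fh.write("time_s,value\n")
            for ti in t:
                fh.write(f"{ti},1.0\n")
        with pytest.raises(ValueError, match="resample"):
            read_series(path)
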