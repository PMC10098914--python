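import numpy as np
import pytest

from ppgresp import (FrequencyBand, IMSParams, SynthConfig, TimeSeries,
                     extract_riav, extract_rifv, extract_riiv, fuse_rivs,
                     generate_ppg, ims_segment, periodogram, pick_rr,
                     segment_signal)
from ppgresp.ims import NoPulsesError, RIVSet, _merge_turning_points
from conftest import as_window, sine_ts

BAND = FrequencyBand(0.05, 0.6)


def brute_force_merge(y):
    """Independent oracle: remove the central point of the first same-sign
    slope triplet found, restart the scan, repeat to a fixed point."""
    pts = list(range(len(y)))
    while True:
        for i in range(len(pts) - 2):
            s1 = np.sign(y[pts[i + 1]] - y[pts[i]])
            s2 = np.sign(y[pts[i + 2]] - y[pts[i + 1]])
            if s1 * s2 > 0:
                del pts[i + 1]
                break
        else:
            return pts


def peak_freq(ts):
    return pick_rr(periodogram(ts), BAND).value / 60.0


class TestSegmentation:
    def test_alternating_square(self):
        tp = ims_segment(as_window([0, 2, 0, 2, 0], fs=1.0), IMSParams(m=1))
        np.testing.assert_allclose(tp.maxima.times, [1, 3], atol=1e-12)
        np.testing.assert_allclose(tp.maxima.values, [2, 2], atol=1e-12)
        np.testing.assert_allclose(tp.minima.times, [0, 2, 4], atol=1e-12)
        np.testing.assert_allclose(tp.minima.values, [0, 0, 0], atol=1e-12)

    def test_monotone_ramp_flags_no_pulses(self):
        with pytest.raises(NoPulsesError, match="no pulses"):
            ims_segment(as_window([0, 1, 2, 3, 4], fs=1.0), IMSParams(m=1))

    def test_sinusoid_cycle_count(self):
        w = as_window(np.sin(2 * np.pi * 1.2 * np.arange(0, 10, 1 / 25)), fs=25.0)
        tp = ims_segment(w, IMSParams(m=1), include_endpoints=False)
        assert abs(len(tp.maxima) - 12) <= 1

    def test_merge_oracle_equivalence(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            y = rng.normal(size=rng.integers(5, 40))
            got = _merge_turning_points(y).tolist()
            assert got == brute_force_merge(y)

    def test_no_same_sign_triplet_survives(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.normal(size=60)
            keep = _merge_turning_points(y)
            s = np.sign(np.diff(y[keep]))
            assert not np.any(s[:-1] * s[1:] > 0)

    def test_maxima_minima_alternate(self, noisy_record):
        from ppgresp import bandpass
        wide = bandpass(noisy_record.ppg, 0.1, 1.5, order=4)
        w = segment_signal(wide, 750, 250)[0]
        tp = ims_segment(w, IMSParams(m=1), include_endpoints=False)
        merged = sorted(
            [(t, "M") for t in tp.maxima.times] + [(t, "m") for t in tp.minima.times]
        )
        kinds = "".join(k for _, k in merged)
        assert "MM" not in kinds and "mm" not in kinds


def beat_events(duration=60.0, f_beat=1.2, amp_fn=None, rate_fn=None):
    """Synthetic turning points: beats from an instantaneous-rate function,
    maxima values from an envelope function, minima at 0."""
    from ppgresp.ims import TurningPoints
    from ppgresp.signals import EventSeries

    t, beats = 0.0, []
    while t < duration:
        beats.append(t)
        f = f_beat * (rate_fn(t) if rate_fn else 1.0)
        t += 1.0 / f
    beats = np.asarray(beats)
    vmax = np.array([amp_fn(tb) if amp_fn else 1.0 for tb in beats])
    return TurningPoints(
        maxima=EventSeries(beats, vmax),
        minima=EventSeries(beats - 0.4, np.zeros_like(beats)),
    )


class TestRIVExtraction:
    def test_riiv_constant_envelope_is_zero(self):
        tp = beat_events()
        out = extract_riiv(tp)
        assert np.max(np.abs(out.values)) < 1e-6

    def test_riiv_recovers_envelope_frequency(self):
        tp = beat_events(amp_fn=lambda t: 1 + 0.2 * np.sin(2 * np.pi * 0.25 * t))
        assert abs(peak_freq(extract_riiv(tp)) - 0.25) < 0.02

    def test_riiv_too_few_maxima(self):
        from ppgresp.ims import TurningPoints
        from ppgresp.signals import EventSeries
        tp = TurningPoints(EventSeries([0.0, 1, 2], [1.0, 1, 1]),
                           EventSeries([0.5, 1.5], [0.0, 0]))
        with pytest.raises(ValueError, match="insufficient"):
            extract_riiv(tp)

    def test_riav_constant_amplitude_is_zero(self):
        out = extract_riav(beat_events())
        assert np.max(np.abs(out.values)) < 1e-6

    def test_riav_recovers_amplitude_modulation(self):
        tp = beat_events(amp_fn=lambda t: 1 + 0.3 * np.sin(2 * np.pi * 0.2 * t))
        assert abs(peak_freq(extract_riav(tp)) - 0.2) < 0.02

    def test_riav_alternans_at_half_beat_rate(self):
        # tall/short alternating pulses modulate amplitude at f_beat / 2
        from ppgresp.ims import TurningPoints
        from ppgresp.signals import EventSeries
        f_b = 1.0
        beats = np.arange(0, 60, 1 / f_b)
        vmax = np.where(np.arange(beats.size) % 2 == 0, 1.5, 0.8)
        tp = TurningPoints(EventSeries(beats, vmax),
                           EventSeries(beats - 0.4, np.zeros_like(beats)))
        riav = extract_riav(tp)
        f = pick_rr(periodogram(riav), FrequencyBand(0.05, 0.6)).value / 60.0
        assert abs(f - f_b / 2) < 0.02

    def test_rifv_regular_beats_is_zero(self):
        out = extract_rifv(beat_events())
        assert np.max(np.abs(out.values)) < 1e-6

    def test_rifv_recovers_rate_modulation(self):
        tp = beat_events(rate_fn=lambda t: 1 + 0.05 * np.sin(2 * np.pi * 0.25 * t))
        assert abs(peak_freq(extract_rifv(tp)) - 0.25) < 0.02

    def test_rifv_too_few_minima(self):
        from ppgresp.ims import TurningPoints
        from ppgresp.signals import EventSeries
        tp = TurningPoints(EventSeries(np.arange(5.0), np.ones(5)),
                           EventSeries(np.arange(4.0) + 0.5, np.zeros(4)))
        with pytest.raises(ValueError, match="insufficient"):
            extract_rifv(tp)


class TestFusion:
    def test_avg_median_arithmetic(self):
        assert fuse_rivs(None, (12, 15, 18), "avg") == 15
        assert fuse_rivs(None, (12, 15, 18), "median") == 15
        assert fuse_rivs(None, (12, 13, 20), "avg") == 15
        assert fuse_rivs(None, (12, 13, 20), "median") == 13

    def test_permutation_invariance(self):
        import itertools
        for perm in itertools.permutations((12.0, 13, 20)):
            assert fuse_rivs(None, perm, "avg") == 15
            assert fuse_rivs(None, perm, "median") == 13

    def test_pca_identical_series(self):
        s = sine_ts(0.25, duration=30, fs=8)
        rivs = RIVSet(riiv=s, riav=s, rifv=s)
        fused = fuse_rivs(rivs, None, "pca")
        c = np.corrcoef(fused.values, s.values)[0, 1]
        assert c > 0.9999

    def test_pca_sign_oriented_to_riiv(self):
        rng = np.random.default_rng(0)
        base = sine_ts(0.25, duration=30, fs=8).values
        rivs = RIVSet(
            riiv=TimeSeries(base + 0.1 * rng.normal(size=base.size), 8.0),
            riav=TimeSeries(-base + 0.1 * rng.normal(size=base.size), 8.0),
            rifv=TimeSeries(base + 0.1 * rng.normal(size=base.size), 8.0),
        )
        fused = fuse_rivs(rivs, None, "pca")
        assert np.corrcoef(fused.values, rivs.riiv.values[:len(fused)])[0, 1] > 0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            fuse_rivs(None, (1, 2, 3), "max")


class TestMechanismRecovery:
    """With one modulation enabled, the matching RIV finds the true rate."""

    @pytest.mark.parametrize("mech,label", [("a_riiv", "riiv"), ("a_riav", "riav"),
                                            ("a_rifv", "rifv")])
    def test_single_mechanism(self, mech, label):
        from ppgresp.cli import PipelineConfig, estimate_record
        kw = dict(a_riiv=0.0, a_riav=0.0, a_rifv=0.0, snr_db=np.inf, seed=5)
        kw[mech] = 0.05 if mech == "a_rifv" else 0.3
        rec = generate_ppg(SynthConfig(**kw))
        df = estimate_record(rec.ppg, PipelineConfig(method="ims"), "v")
        med = df.groupby("estimator")["rr_bpm"].median()
        est = med[f"RR_{label.upper()}"]
        assert abs(est / 60.0 - 0.25) < 0.02
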