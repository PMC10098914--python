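"""Periodogram PSD estimation and respiratory-rate peak picking.

RR is read off the power spectral density of a (post-processed) respiratory
waveform as 60 times the frequency of the most prominent in-band peak.  The
respiratory search band adapts to the heart rate extracted from the same
signal: [0.1, min(0.6, HR/2)] Hz, which keeps the search region below the
first cardiac harmonic while bounding plausible resting rates at
36 breaths/min; when no cardiac peak is found the fixed quality-control band
[0.1, 0.5] Hz is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram as _sp_periodogram

from .signals import TimeSeries

__all__ = [
    "PSD",
    "FrequencyBand",
    "RREstimate",
    "CARDIAC_BAND",
    "FALLBACK_BAND",
    "periodogram",
    "estimate_hr",
    "adaptive_band",
    "pick_rr",
    "aggregate_video",
]

#: Search band for the cardiac peak, Hz (42-180 beats/min).
CARDIAC_BAND = (0.7, 3.0)
#: Respiratory band when HR is unavailable, Hz.
FALLBACK_BAND = (0.1, 0.5)
#: Zero-padding factor of the periodogram (finer frequency grid).
PAD_FACTOR = 4


@dataclass(frozen=True)
class FrequencyBand:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError("invalid band: need 0 <= lo < hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo) & (freqs <= self.hi)


@dataclass(frozen=True)
class PSD:
    freqs: np.ndarray
    power: np.ndarray


@dataclass(frozen=True)
class RREstimate:
    """A respiratory-rate value in breaths/min with provenance.

    ``value`` is NaN when no in-band spectral peak exists (undefined
    estimate); ``defined`` distinguishes that case.
    """

    value: float
    estimator: str = ""
    window_index: int = -1
    peak_power: float = float("nan")

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


UNDEFINED = RREstimate(value=float("nan"))


def periodogram(ts: TimeSeries) -> PSD:
    """Periodogram of the mean-removed series, rectangular window.

    The FFT is zero-padded to four times the series length so that the
    frequency grid does not quantize the RR estimate.
    """
    if len(ts) < 32:
        raise ValueError("series too short for a periodogram (need >= 32 samples)")
    f, p = _sp_periodogram(
        ts.values, fs=ts.fs, window="boxcar", detrend="constant",
        nfft=PAD_FACTOR * len(ts),
    )
    return PSD(freqs=f, power=p)


def estimate_hr(ts: TimeSeries) -> float:
    """Heart rate (Hz) as the periodogram peak inside the cardiac band.

    Returns NaN when no meaningful cardiac peak exists (all in-band power
    zero or the band empty), signalling the caller to fall back to the fixed
    respiratory band.
    """
    psd = periodogram(ts)
    band = FrequencyBand(*CARDIAC_BAND)
    m = band.mask(psd.freqs)
    if not m.any() or not np.any(psd.power[m] > 0):
        return float("nan")
    k = int(np.flatnonzero(m)[np.argmax(psd.power[m])])
    # a genuine cardiac peak is a local maximum of the full spectrum (the
    # in-band argmax of pure out-of-band leakage sits at the band edge) and
    # stands clear of the in-band noise floor
    if 0 < k < psd.power.size - 1:
        if psd.power[k] < psd.power[k - 1] or psd.power[k] < psd.power[k + 1]:
            return float("nan")
    # spectral-leakage side lobes of a strong out-of-band tone are local
    # maxima too, but orders of magnitude below the global peak
    if psd.power[k] < 0.05 * np.max(psd.power):
        return float("nan")
    return float(psd.freqs[k])


def adaptive_band(hr_hz: float) -> FrequencyBand:
    """HR-adaptive respiratory band [0.1, min(0.6, HR/2)] Hz, with fallback."""
    if not np.isfinite(hr_hz):
        return FrequencyBand(*FALLBACK_BAND)
    return FrequencyBand(0.1, min(0.6, hr_hz / 2.0))


def pick_rr(
    psd: PSD,
    band: FrequencyBand,
    estimator: str = "",
    window_index: int = -1,
) -> RREstimate:
    """RR (breaths/min) = 60 x the frequency of the strongest in-band peak."""
    m = band.mask(psd.freqs)
    if not m.any():
        return RREstimate(float("nan"), estimator, window_index)
    in_f, in_p = psd.freqs[m], psd.power[m]
    k = int(np.argmax(in_p))
    if not (in_p[k] > 0):
        return RREstimate(float("nan"), estimator, window_index)
    return RREstimate(60.0 * float(in_f[k]), estimator, window_index, float(in_p[k]))


def rr_of_series(
    ts: TimeSeries,
    band: FrequencyBand,
    estimator: str = "",
    window_index: int = -1,
) -> RREstimate:
    """Convenience: periodogram + in-band peak pick of one waveform."""
    try:
        psd = periodogram(ts)
    except ValueError:
        return RREstimate(float("nan"), estimator, window_index)
    return pick_rr(psd, band, estimator, window_index)


def aggregate_video(estimates: list[RREstimate] | list[float]) -> float:
    """Per-video RR: median of the defined per-window estimates.

    Raises ``ValueError`` when no window produced a defined estimate, so the
    caller can skip (and log) the video.
    """
    vals = [e.value if isinstance(e, RREstimate) else float(e) for e in estimates]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        raise ValueError("no defined window estimates to aggregate")
    return float(np.median(vals))
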