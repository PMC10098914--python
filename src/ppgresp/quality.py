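"""Reliability screening of respiratory reference signals.

Thoracic-impedance respiratory references are frequently corrupted by motion
and electrode artifacts, so before a recording is allowed to serve as ground
truth it is screened: band-pass filtered to the breathing band
(0.1-0.5 Hz, second-order Butterworth), normalized to [-1, 1], and reduced to
peak/trough statistics.  A recording is rejected as corrupted when the
standard deviation of its peak-to-peak intervals exceeds 1 s (irregular or
missing breath cycles) or the standard deviation of its trough heights
exceeds 0.2 normalized units (baseline instability), and unconditionally when
it is shorter than 30 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signals import TimeSeries, bandpass, normalize_range

__all__ = ["QCReport", "qc_respiratory", "QC_BAND", "QC_FILTER_ORDER",
           "SIGMA1_MAX", "SIGMA2_MAX", "MIN_DURATION_S"]

QC_BAND = (0.1, 0.5)
QC_FILTER_ORDER = 2
SIGMA1_MAX = 1.0    # s, max std of peak-to-peak intervals
SIGMA2_MAX = 0.2    # normalized units, max std of trough heights
MIN_DURATION_S = 30.0
#: Minimum extremum separation: half a period at the band's upper edge.
_MIN_PEAK_DISTANCE_S = 1.0 / (2 * QC_BAND[1])
#: Edge margin (s) excluded from peak/trough statistics: the zero-phase
#: band-pass settles over roughly one period of its low cut-off.
_EDGE_MARGIN_S = 3.0


@dataclass(frozen=True)
class QCReport:
    sigma1: float
    sigma2: float
    duration: float
    accepted: bool
    reason: str = ""


def qc_respiratory(ts: TimeSeries) -> QCReport:
    """Screen one respiratory reference; see the module docstring for the rule."""
    duration = ts.duration
    if duration < MIN_DURATION_S:
        return QCReport(float("nan"), float("nan"), duration, False, "duration")

    filtered = bandpass(ts, *QC_BAND, order=QC_FILTER_ORDER)
    raw_scale = float(np.std(ts.values))
    if raw_scale == 0 or np.std(filtered.values) <= 1e-9 * raw_scale:
        return QCReport(float("nan"), float("nan"), duration, False, "no breathing cycles")
    norm = normalize_range(filtered)

    dist = max(1, int(round(_MIN_PEAK_DISTANCE_S * ts.fs)))
    margin = int(round(_EDGE_MARGIN_S * ts.fs))
    peaks, _ = find_peaks(norm.values, distance=dist)
    troughs, _ = find_peaks(-norm.values, distance=dist)
    peaks = peaks[(peaks >= margin) & (peaks < len(norm.values) - margin)]
    troughs = troughs[(troughs >= margin) & (troughs < len(norm.values) - margin)]
    if peaks.size < 2 or troughs.size < 1:
        return QCReport(float("nan"), float("nan"), duration, False, "no breathing cycles")

    sigma1 = float(np.std(np.diff(peaks) / ts.fs, ddof=1)) if peaks.size >= 3 else 0.0
    sigma2 = float(np.std(norm.values[troughs], ddof=1)) if troughs.size >= 2 else 0.0

    if sigma1 > SIGMA1_MAX:
        return QCReport(sigma1, sigma2, duration, False, "sigma1")
    if sigma2 > SIGMA2_MAX:
        return QCReport(sigma1, sigma2, duration, False, "sigma2")
    return QCReport(sigma1, sigma2, duration, True, "")
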