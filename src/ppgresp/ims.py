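"""Incremental Merge Segmentation (IMS) and respiratory-induced-variation extraction.

IMS locates pulse extrema in a PPG window by a slope-sign merging rule: the
window is subsampled with stride ``m``, consecutive-point slopes are computed,
and the central point of every triplet whose two slopes share a sign is
removed, iteratively, until only turning points survive.  Beats correspond to
the end of a run of positive-gradient segments (systolic upslope).

From the surviving maxima/minima three respiratory waveforms are built and
passed through the artifact-reduction operator Pi:

* RIIV -- the maxima-value envelope (baseline / intensity modulation),
* RIAV -- maximum minus preceding minimum (pulse-amplitude modulation),
* RIFV -- inter-minima intervals, i.e. a tachogram (respiratory sinus
  arrhythmia / frequency modulation).

Each waveform yields a spectral RR estimate; the three are fused as the mean,
the median (of the RR values) or the first principal component (of the
waveforms themselves), giving the six IMS estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import EventSeries, TimeSeries, Window, artifact_reduce, RIV_RESAMPLE_FS

__all__ = [
    "IMSParams",
    "TurningPoints",
    "RIVSet",
    "NoPulsesError",
    "ims_segment",
    "refine_beat_times",
    "extract_riiv",
    "extract_riav",
    "extract_rifv",
    "extract_rivs",
    "fuse_rivs",
    "default_stride",
]


class NoPulsesError(ValueError):
    """Raised when a window contains no detectable pulse extrema."""


@dataclass(frozen=True)
class IMSParams:
    """IMS configuration: subsampling stride ``m`` in samples (>= 1)."""

    m: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("stride m must be >= 1")


@dataclass(frozen=True)
class TurningPoints:
    """Alternating pulse extrema: maxima and minima as (time, value) events."""

    maxima: EventSeries
    minima: EventSeries


@dataclass(frozen=True)
class RIVSet:
    """The three respiratory-induced-variation waveforms on uniform grids."""

    riiv: TimeSeries
    riav: TimeSeries
    rifv: TimeSeries

    def as_dict(self) -> dict[str, TimeSeries]:
        return {"RIIV": self.riiv, "RIAV": self.riav, "RIFV": self.rifv}


def default_stride(fs: float, target_rate: float = 25.0) -> int:
    """Stride giving ~25 strided points per second (>= 12 points per cardiac cycle)."""
    return max(1, int(round(fs / target_rate)))


def _merge_turning_points(y: np.ndarray) -> np.ndarray:
    """Indices (into y) of points surviving iterative same-sign-slope removal.

    Repeatedly deletes the central point of any triplet whose two slopes have
    the same sign until no such triplet remains; survivors are the turning
    points of the strided sequence.  A single left-to-right sweep removes all
    interior points of each monotone run; sweeps repeat until stable so that
    runs merged across a removed point are handled too.
    """
    keep = list(range(y.size))
    changed = True
    while changed and len(keep) >= 3:
        changed = False
        out = [keep[0]]
        for idx in range(1, len(keep) - 1):
            a, b, c = y[out[-1]], y[keep[idx]], y[keep[idx + 1]]
            if np.sign(b - a) * np.sign(c - b) > 0:
                changed = True  # same-sign slopes: drop the central point
            else:
                out.append(keep[idx])
        out.append(keep[-1])
        keep = out
    return np.asarray(keep, dtype=int)


#: Half-width (seconds) of the least-squares parabola used for sub-sample
#: extremum refinement; ~1/7 of a resting beat period.
_REFINE_HALF_S = 0.12


def _ls_parabola_refine(
    times: np.ndarray, y: np.ndarray, k: int, dt: float, half: int
) -> tuple[float, float]:
    """Sub-sample extremum location from a least-squares parabola fit.

    Beat-interval modulation (respiratory sinus arrhythmia) is only a few
    percent of the beat period -- comparable to one sample step at video
    frame rates -- so extremum times quantized to the grid would bury the
    tachogram in quantization noise.  Fitting the parabola over a +-half
    neighbourhood additionally averages down additive-noise timing jitter.
    """
    lo, hi = max(0, k - half), min(y.size, k + half + 1)
    tt = np.arange(lo, hi, dtype=float) - k
    A = np.vstack([tt**2, tt, np.ones_like(tt)]).T
    (a, b, c), *_ = np.linalg.lstsq(A, y[lo:hi], rcond=None)
    if a == 0:
        return times[k], y[k]
    delta = float(np.clip(-b / (2 * a), -half, half))
    return times[k] + delta * dt, a * delta**2 + b * delta + c


def ims_segment(
    w: Window,
    params: IMSParams | None = None,
    refine: bool = True,
    include_endpoints: bool = True,
) -> TurningPoints:
    """Detect pulse extrema in a window by incremental merge segmentation.

    Returns the surviving turning points split into maxima and minima, with
    times in seconds (absolute in the parent signal).  Interior survivors
    are classified against both neighbours; with ``include_endpoints``
    (default) the two boundary survivors are classified one-sidedly so the
    max/min alternation extends to the window edges.  Edge survivors are
    where the window cuts the waveform, not true pulse landmarks, so
    pipeline callers may prefer ``include_endpoints=False``.

    With ``refine`` (default) each extremum's time and value are moved to
    sub-sample precision by a least-squares parabola over its strided
    neighbourhood; the set of detected extrema is unaffected.

    Raises
    ------
    NoPulsesError
        If the (strided) window is monotone and no interior extrema survive.
    """
    params = params or IMSParams(m=default_stride(w.fs))
    if params.m >= len(w):
        raise ValueError("stride m must be smaller than the window length")
    idx = np.arange(0, len(w), params.m)
    if idx.size < 3:
        raise NoPulsesError("no pulses detected: fewer than 3 strided points")
    y = w.values[idx]
    survivors = _merge_turning_points(y)
    if survivors.size <= 2:
        raise NoPulsesError("no pulses detected: window is monotone")
    chosen = survivors if include_endpoints else survivors[1:-1]

    times = w.times[idx]
    dt = params.m / w.fs
    half = max(1, int(round(_REFINE_HALF_S / dt)))
    is_max = np.empty(chosen.size, dtype=bool)
    ref_t = np.empty(chosen.size)
    ref_v = np.empty(chosen.size)
    for n, k in enumerate(chosen):
        pos = int(np.searchsorted(survivors, k))
        left = y[survivors[pos - 1]] if pos > 0 else None
        right = y[survivors[pos + 1]] if pos < survivors.size - 1 else None
        above = [y[k] > v for v in (left, right) if v is not None]
        is_max[n] = bool(above) and all(above)
        if refine and 0 < k < y.size - 1 and left is not None and right is not None:
            ref_t[n], ref_v[n] = _ls_parabola_refine(times, y, k, dt, half)
        else:
            ref_t[n], ref_v[n] = times[k], y[k]
    maxima = EventSeries(ref_t[is_max], ref_v[is_max])
    minima = EventSeries(ref_t[~is_max], ref_v[~is_max])
    return TurningPoints(maxima=maxima, minima=minima)


def refine_beat_times(
    tp: TurningPoints,
    timing: Window | TimeSeries,
    start_time: float = 0.0,
    search_s: float = 0.2,
) -> TurningPoints:
    """Re-time the extrema on a cardiac-narrowband version of the window.

    The beat-interval waveform (tachogram) carries respiratory modulation of
    only a few percent of the beat period, so out-of-band noise -- slow
    baseline wander as much as high-frequency noise -- jitters extremum
    times enough to bury it.  Pulse timing needs only the cardiac component:
    each extremum is relocated to the nearest extremum of ``timing`` (the
    same window filtered to a narrow band around the heart rate), with
    sub-sample least-squares parabola interpolation.  Extremum values are
    left untouched; only times move, by at most ``search_s`` seconds.
    """
    if isinstance(timing, Window):
        t0 = timing.start / timing.fs
        yt = timing.values
        fs = timing.fs
    else:
        t0 = start_time
        yt = timing.values
        fs = timing.fs
    dt = 1.0 / fs
    half = max(1, int(round(_REFINE_HALF_S / dt)))
    search = max(1, int(round(search_s * fs)))

    def relocate(ev: EventSeries, sign: float) -> EventSeries:
        new_t = np.empty(len(ev))
        for n, te in enumerate(ev.times):
            k0 = int(round((te - t0) * fs))
            lo, hi = max(0, k0 - search), min(yt.size, k0 + search + 1)
            if hi - lo < 3:
                new_t[n] = te
                continue
            k = lo + int(np.argmax(sign * yt[lo:hi]))
            lo2, hi2 = max(0, k - half), min(yt.size, k + half + 1)
            tt = np.arange(lo2, hi2, dtype=float) - k
            A = np.vstack([tt**2, tt, np.ones_like(tt)]).T
            (a, b, _), *_ = np.linalg.lstsq(A, yt[lo2:hi2], rcond=None)
            delta = float(np.clip(-b / (2 * a), -half, half)) if a != 0 else 0.0
            new_t[n] = t0 + (k + delta) * dt
        keep = np.concatenate([[True], np.diff(new_t) > 0])
        return EventSeries(new_t[keep], ev.values[keep])

    return TurningPoints(maxima=relocate(tp.maxima, +1.0),
                         minima=relocate(tp.minima, -1.0))


def extract_riiv(tp: TurningPoints, out_fs: float = RIV_RESAMPLE_FS) -> TimeSeries:
    """RIIV: Pi applied to the maxima-value (baseline-intensity) envelope."""
    if len(tp.maxima) < 4:
        raise ValueError("insufficient beats: need >= 4 maxima for RIIV")
    ts = artifact_reduce(tp.maxima, out_fs=out_fs)
    return ts.with_values(ts.values, label="RIIV")


def extract_riav(tp: TurningPoints, out_fs: float = RIV_RESAMPLE_FS) -> TimeSeries:
    """RIAV: Pi applied to the pulse-amplitude series.

    Each maximum is paired with the immediately preceding minimum (the
    systolic upslope); the difference max - min is timestamped at the
    maximum.  Unpaired extrema at the window edges are dropped.
    """
    t_max, v_max = tp.maxima.times, tp.maxima.values
    t_min, v_min = tp.minima.times, tp.minima.values
    if len(t_min) == 0:
        raise ValueError("insufficient beats: no minima to pair")
    prev = np.searchsorted(t_min, t_max) - 1
    ok = prev >= 0
    if np.count_nonzero(ok) < 4:
        raise ValueError("insufficient beats: need >= 4 max-min pairs for RIAV")
    amp = v_max[ok] - v_min[prev[ok]]
    ts = artifact_reduce(EventSeries(t_max[ok], amp), out_fs=out_fs)
    return ts.with_values(ts.values, label="RIAV")


def extract_rifv(tp: TurningPoints, out_fs: float = RIV_RESAMPLE_FS) -> TimeSeries:
    """RIFV: Pi applied to the inter-minima tachogram.

    Intervals between consecutive minima (absolute value, in seconds) are
    timestamped at the interval midpoints, then resampled through Pi.
    """
    t_min = tp.minima.times
    if len(t_min) < 5:
        raise ValueError("insufficient beats: need >= 5 minima for RIFV")
    intervals = np.abs(np.diff(t_min))
    mids = 0.5 * (t_min[:-1] + t_min[1:])
    ts = artifact_reduce(EventSeries(mids, intervals), out_fs=out_fs)
    return ts.with_values(ts.values, label="RIFV")


def extract_rivs(tp: TurningPoints, out_fs: float = RIV_RESAMPLE_FS) -> RIVSet:
    """All three RIV waveforms from one set of turning points."""
    return RIVSet(
        riiv=extract_riiv(tp, out_fs),
        riav=extract_riav(tp, out_fs),
        rifv=extract_rifv(tp, out_fs),
    )


def fuse_rivs(
    rivs: RIVSet | None,
    rr_per_riv: tuple[float, float, float] | None,
    mode: str,
) -> float | TimeSeries:
    """Fuse the three RIV channels into one estimator.

    ``avg`` / ``median`` combine the three per-RIV RR values (breaths/min)
    arithmetically.  ``pca`` stacks the standardized RIV waveforms as three
    realizations of the respiratory trend and returns the first principal
    component as a fused waveform for spectral RR estimation; its sign is
    oriented to correlate positively with RIIV for determinism.

    The decomposition is the SVD of the standardized 3 x N stack without
    re-centering across the three realizations: each series is already
    zero-mean in time, and removing the ensemble mean would subtract the very
    trend the channels share (three identical series must map to themselves).
    """
    if mode in ("avg", "median"):
        if rr_per_riv is None or len(rr_per_riv) != 3:
            raise ValueError("avg/median fusion needs the three per-RIV RR values")
        arr = np.asarray(rr_per_riv, dtype=float)
        return float(np.mean(arr) if mode == "avg" else np.median(arr))
    if mode != "pca":
        raise ValueError(f"unknown fusion mode {mode!r}")
    if rivs is None:
        raise ValueError("pca fusion needs the RIV waveforms")
    series = [rivs.riiv, rivs.riav, rivs.rifv]
    fs = series[0].fs
    if any(s.fs != fs for s in series):
        raise ValueError("RIV series must share a sampling rate for PCA fusion")
    n = min(len(s) for s in series)
    X = np.vstack([s.values[:n] for s in series])
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = vt[0]
    if np.dot(pc1, X[0]) < 0:  # orient toward RIIV
        pc1 = -pc1
    return TimeSeries(pc1, fs=fs, label="RIV_PCA")
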