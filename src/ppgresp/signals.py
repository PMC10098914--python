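"""Core time-series containers, windowing, filtering and the artifact-reduction operator.

Everything downstream (pulse segmentation, mode decomposition, spectral RR
picking) exchanges data through two containers: :class:`TimeSeries` for
uniformly sampled signals and :class:`EventSeries` for irregular
(time, value) pairs such as beat-peak sequences.  The artifact-reduction
operator Pi -- the first derivative of a cubic-spline interpolant evaluated
on a uniform grid -- lives here because every respiratory-variation waveform
passes through it before spectral analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "TimeSeries",
    "EventSeries",
    "Window",
    "WindowPlan",
    "segment_signal",
    "bandpass",
    "normalize_range",
    "artifact_reduce",
    "read_series",
    "write_series",
    "RIV_RESAMPLE_FS",
]

#: Uniform grid rate (Hz) for series reconstructed from beat events.
#: Respiratory content lives below 1 Hz; 8 Hz leaves comfortable margin.
RIV_RESAMPLE_FS = 8.0


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal with its sampling rate.

    Parameters
    ----------
    values : array-like
        Sample values (arbitrary units).
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str
        Free-text provenance tag carried through the pipeline.
    """

    values: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("TimeSeries requires a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n samples / fs)."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self)) / self.fs

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)


@dataclass(frozen=True)
class EventSeries:
    """Irregularly timed (time, value) pairs, times strictly increasing."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equally long")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window layout: length M, shift K, segment count S.

    Adjacent windows overlap by ``M - K`` samples; window ``j`` starts at
    sample ``j * K``.  ``S = floor((T - M) / K) + 1``.
    """

    M: int
    K: int
    T: int
    S: int = field(init=False)

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("invalid shift: K must be >= 1")
        if not (0 < self.M <= self.T):
            raise ValueError("window longer than signal")
        object.__setattr__(self, "S", (self.T - self.M) // self.K + 1)


@dataclass(frozen=True)
class Window:
    """Segment ``j`` of a parent signal: M samples starting at offset j*K."""

    j: int
    values: np.ndarray
    start: int
    fs: float

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Absolute times (seconds) of the window samples in the parent signal."""
        return (self.start + np.arange(len(self))) / self.fs

    def as_timeseries(self, label: str = "") -> TimeSeries:
        return TimeSeries(self.values, self.fs, label=label)


def segment_signal(ts: TimeSeries, M: int, K: int) -> list[Window]:
    """Split a signal into overlapping windows of M samples shifted by K.

    Returns ``S = floor((T - M) / K) + 1`` windows; trailing samples that do
    not fill a complete window are dropped.
    """
    plan = WindowPlan(M=int(M), K=int(K), T=len(ts))
    return [
        Window(j=j, values=ts.values[j * plan.K: j * plan.K + plan.M],
               start=j * plan.K, fs=ts.fs)
        for j in range(plan.S)
    ]


def bandpass(ts: TimeSeries, low: float, high: float, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``) so that peak
    timing -- which the pulse segmentation and the beat-interval tachogram
    depend on -- is preserved.  The effective magnitude response is the
    squared response of the designed filter.
    """
    nyq = ts.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"invalid band: need 0 < low < high < fs/2, got ({low}, {high}) at fs={ts.fs}"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=ts.fs, output="sos")
    # reflect-pad over ~3 periods of the low cut-off so the slow edge
    # transient settles outside the signal
    padlen = min(len(ts) - 1, int(round(3.0 * ts.fs / low)))
    return ts.with_values(sosfiltfilt(sos, ts.values, padlen=padlen))


def normalize_range(ts: TimeSeries) -> TimeSeries:
    """Affine rescale onto [-1, 1]: the minimum maps to -1, the maximum to +1."""
    lo, hi = ts.values.min(), ts.values.max()
    if hi <= lo:
        raise ValueError("degenerate range: constant signal cannot be normalized")
    return ts.with_values(2.0 * (ts.values - lo) / (hi - lo) - 1.0)


def artifact_reduce(
    series: EventSeries | TimeSeries,
    out_fs: float = RIV_RESAMPLE_FS,
) -> TimeSeries:
    """Artifact-reduction operator Pi: derivative of the cubic-spline interpolant.

    A natural cubic spline (not-a-knot ends) is fitted through the points and
    its analytic first derivative is evaluated on a uniform grid at
    ``out_fs``.  Pi simultaneously resamples irregular beat-event series onto
    a uniform grid and suppresses slow baseline trends (differentiation kills
    the constant/near-DC component), which is why every respiratory-variation
    waveform is passed through it before spectral RR estimation.
    """
    if isinstance(series, TimeSeries):
        t, v = series.times, series.values
    else:
        t, v = series.times, series.values
    if t.size < 4:
        raise ValueError("insufficient points for spline (need >= 4)")
    spline = CubicSpline(t, v, bc_type="not-a-knot")
    grid = np.arange(t[0], t[-1], 1.0 / out_fs)
    if grid.size < 2:
        raise ValueError("insufficient points for spline (span too short)")
    return TimeSeries(spline(grid, 1), fs=out_fs, label="pi")


# ---------------------------------------------------------------------------
# File I/O: two-column delimited text (time_s, value) and .npz containers
# ---------------------------------------------------------------------------

#: Tolerated relative jitter of the time column around the median step.
_MAX_TIME_JITTER = 0.01


def write_series(ts: TimeSeries, path: str | Path, format: str | None = None) -> None:
    """Write a series as two-column CSV ``time_s,value`` or as a ``.npz`` container."""
    path = Path(path)
    fmt = format or ("npz" if path.suffix == ".npz" else "csv")
    if fmt == "npz":
        np.savez(path, values=ts.values, fs=ts.fs, label=ts.label)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "value"])
            for t, v in zip(ts.times, ts.values):
                w.writerow([f"{t:.9g}", f"{v:.12g}"])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_series(path: str | Path, format: str | None = None, label: str = "") -> TimeSeries:
    """Read a series written by :func:`write_series`.

    CSV files may carry a one-line header; the sampling rate is inferred from
    the time column, which must be uniform to within 1% jitter.
    """
    path = Path(path)
    fmt = format or ("npz" if path.suffix == ".npz" else "csv")
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            if "fs" not in z:
                raise ValueError(f"{path}: container is missing the fs attribute")
            lab = str(z["label"]) if "label" in z else label
            return TimeSeries(z["values"], float(z["fs"]), label=lab or label)
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    t, v = _read_two_column_csv(path)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > _MAX_TIME_JITTER * step:
        raise ValueError(
            f"{path}: non-uniform sampling (jitter > 1% of the median step); "
            "resample onto a uniform grid first"
        )
    return TimeSeries(v, fs=1.0 / step, label=label or path.stem)


def _read_two_column_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#"):
                continue
            try:
                t, v = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                if not times:  # tolerate a single header line
                    continue
                raise ValueError(f"{path}: malformed row {row!r}")
            times.append(t)
            values.append(v)
    return np.asarray(times), np.asarray(values)
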