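"""Empirical Mode Decomposition by iterative sifting, capped at four modes.

EMD decomposes a window x(t) into intrinsic mode functions (IMFs) h_k(t) and
a residual trend r(t):  x = sum_k h_k + r.  One IMF is extracted by
"sifting": fit cubic-spline envelopes through the local maxima and minima,
subtract the envelope mean, and repeat on the result until the candidate is
locally symmetric.  Convergence is judged by the normalized squared change
between consecutive candidates,

    SD_i = sum_t (d_i(t) - d_{i-1}(t))^2 / d_{i-1}(t)^2  <=  0.1,

evaluated from the second iteration on, with an epsilon guard against zero
denominators.  Decomposition stops after four IMFs or when the residual is
monotone / has fewer than two maxima or minima.  The construction is purely
subtractive, so the reconstruction identity holds to rounding error.

For respiratory-rate use, each IMF yields a spectral RR estimate in the
respiratory band; the mode whose in-band peak carries the most power gives
the combined EMD estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .signals import TimeSeries, Window

__all__ = ["EMDResult", "sift", "emd_decompose", "rr_from_emd", "local_extrema_indices"]

#: Guard added to the squared denominator of the sifting stop criterion.
_SD_EPS = 1e-12


@dataclass(frozen=True)
class EMDResult:
    """Ordered IMFs plus the residual trend; their sum reconstructs the input."""

    imfs: list[TimeSeries]
    residual: TimeSeries

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.values.copy()
        for imf in self.imfs:
            out += imf.values
        return out


def local_extrema_indices(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of a 1-D array.

    Flat-topped extrema (plateaus) are reported once, at the plateau centre,
    by comparing against the nearest unequal neighbours.
    """
    n = v.size
    if n < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.diff(v)
    # carry the sign of the last nonzero step across plateaus
    sign = np.sign(d)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    maxima = flips[sign[flips] < 0]
    minima = flips[sign[flips] > 0]
    return maxima, minima


def _envelope(t: np.ndarray, v: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema at ``idx``, mirror-extended.

    The first/last two extrema are reflected about the series endpoints
    before spline fitting, the usual defence against end swings.
    """
    te, ve = t[idx], v[idx]
    if te.size >= 2:
        left_t = 2 * t[0] - te[1::-1]
        left_v = ve[1::-1]
        right_t = 2 * t[-1] - te[:-3:-1]
        right_v = ve[:-3:-1]
        # drop mirrored knots that collide with real ones at the boundary
        keep_l = left_t < te[0]
        keep_r = right_t > te[-1]
        te = np.concatenate([left_t[keep_l], te, right_t[keep_r]])
        ve = np.concatenate([left_v[keep_l], ve, right_v[keep_r]])
    return CubicSpline(te, ve, bc_type="not-a-knot")(t)


def sift(v: TimeSeries, sd_threshold: float = 0.1, max_iter: int = 50) -> TimeSeries:
    """Extract one IMF from ``v`` by iterative envelope-mean subtraction.

    Stops when the normalized squared change between consecutive candidates
    drops to ``sd_threshold`` (default 0.1) or after ``max_iter`` iterations.

    Raises
    ------
    ValueError
        If the input has fewer than two maxima or two minima ("cannot sift").
    """
    t = v.times
    cur = v.values.astype(float).copy()
    prev = None
    for _ in range(max_iter):
        mx, mn = local_extrema_indices(cur)
        if mx.size < 2 or mn.size < 2:
            if prev is None:
                raise ValueError("cannot sift: fewer than 2 maxima or 2 minima")
            break
        mean_env = 0.5 * (_envelope(t, cur, mx) + _envelope(t, cur, mn))
        cand = cur - mean_env
        if prev is not None:
            sd = float(np.sum((cand - cur) ** 2 / (cur**2 + _SD_EPS)))
            if sd <= sd_threshold:
                cur = cand
                break
        prev = cur
        cur = cand
    return v.with_values(cur, label="imf")


def _is_monotone_or_extrema_poor(v: np.ndarray) -> bool:
    mx, mn = local_extrema_indices(v)
    return mx.size < 2 or mn.size < 2


def emd_decompose(
    w: Window | TimeSeries,
    max_imfs: int = 4,
    sd_threshold: float = 0.1,
    max_iter: int = 50,
) -> EMDResult:
    """Full EMD of a window: repeated sifting of the running residual.

    Extraction stops at ``max_imfs`` modes (default four) or as soon as the
    residual is monotone or has fewer than two local maxima or minima.  The
    residual of each step is ``r = v - h_k`` so that IMFs + residual always
    reconstruct the input exactly (up to floating-point rounding).
    """
    ts = w.as_timeseries() if isinstance(w, Window) else w
    if len(ts) < 64:
        raise ValueError("window too short for EMD (need >= 64 samples)")
    residual = ts.values.astype(float).copy()
    imfs: list[TimeSeries] = []
    for _ in range(max_imfs):
        if _is_monotone_or_extrema_poor(residual):
            break
        imf = sift(ts.with_values(residual), sd_threshold=sd_threshold, max_iter=max_iter)
        imfs.append(imf.with_values(imf.values, label=f"IMF{len(imfs) + 1}"))
        residual = residual - imf.values
    return EMDResult(imfs=imfs, residual=ts.with_values(residual, label="residual"))


def rr_from_emd(
    res: EMDResult,
    band,
    select: str = "power",
    window_index: int = -1,
    postprocess: bool = False,
):
    """Per-IMF respiratory rates and the combined EMD estimate.

    Each IMF yields an in-band spectral RR estimate; the combined value
    ``RR_EMD`` is the per-IMF estimate whose spectral peak carries the most
    power (``select="power"``, default) or the highest estimated frequency
    (``select="frequency"``).  With ``postprocess=True`` each IMF is first
    passed through the artifact-reduction operator Pi.

    Returns ``(rr_emd, per_imf)`` where ``per_imf`` maps labels RR_IMF1.. to
    their estimates; undefined estimates carry NaN.
    """
    from .signals import artifact_reduce
    from .spectral import RREstimate, rr_of_series

    if res.n_imfs < 1:
        raise ValueError("need at least one IMF")
    per_imf: dict[str, RREstimate] = {}
    for k, imf in enumerate(res.imfs, start=1):
        series = imf
        if postprocess:
            try:
                series = artifact_reduce(imf)
            except ValueError:
                series = imf
        per_imf[f"RR_IMF{k}"] = rr_of_series(
            series, band, estimator=f"RR_IMF{k}", window_index=window_index
        )
    defined = [e for e in per_imf.values() if e.defined]
    if not defined:
        combined = RREstimate(float("nan"), "RR_EMD", window_index)
    else:
        key = (lambda e: e.peak_power) if select == "power" else (lambda e: e.value)
        best = max(defined, key=key)
        combined = RREstimate(best.value, "RR_EMD", window_index, best.peak_power)
    return combined, per_imf
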