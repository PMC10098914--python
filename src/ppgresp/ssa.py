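"""Singular Spectrum Analysis: lag embedding, SVD, diagonal averaging.

A window x of length M is embedded into the L x K trajectory (Hankel) matrix
(K = M - L + 1) whose columns are the lagged vectors (x_i, ..., x_{i+L-1}).
SVD splits the trajectory matrix into rank-1 elementary matrices
X_i = s_i U_i V_i^T; Hankelization (anti-diagonal averaging) of each X_i
returns an additive component series z_i of length M.  The left singular
vectors U_i are the empirical orthogonal functions (EOFs).  No component
grouping is applied: every elementary matrix becomes its own component, and
only the leading few (default three) are used for respiratory-rate
estimation -- in practice the first EOF usually carries the cardiac
oscillation and the second the baseline respiratory modulation.

Since SVD is exact and averaging is linear, the components sum back to the
original window to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel

from .signals import TimeSeries, Window

__all__ = ["Trajectory", "SSAResult", "embed", "decompose", "hankelize",
           "ssa_components", "rr_from_ssa", "wcorr"]


@dataclass(frozen=True)
class Trajectory:
    """L x (M - L + 1) Hankel trajectory matrix of a window."""

    X: np.ndarray
    L: int
    fs: float
    start: int = 0

    @property
    def K_lag(self) -> int:
        return self.X.shape[1]

    @property
    def M(self) -> int:
        return self.L + self.K_lag - 1


@dataclass(frozen=True)
class SSAResult:
    """Singular triplets and the Hankelized component series.

    ``singular_values`` are non-increasing; ``eofs`` (columns of U) are the
    empirical orthogonal functions; ``components[i]`` is the series obtained
    by diagonal averaging of the i-th elementary matrix.  The components are
    an exact additive decomposition of the analysed window.
    """

    singular_values: np.ndarray
    eofs: np.ndarray
    components: list[TimeSeries]
    n_keep: int = 3

    @property
    def d(self) -> int:
        return self.singular_values.size

    def reconstruct(self) -> np.ndarray:
        return np.sum([c.values for c in self.components], axis=0)


def embed(w: Window | TimeSeries | np.ndarray, L: int, fs: float | None = None) -> Trajectory:
    """Build the Hankel trajectory matrix with embedding length ``L`` (1 < L <= M)."""
    if isinstance(w, (Window, TimeSeries)):
        v = w.values
        fs = w.fs
        start = w.start if isinstance(w, Window) else 0
    else:
        v = np.asarray(w, dtype=float)
        fs = fs or 1.0
        start = 0
    M = v.size
    if not (1 < L <= M):
        raise ValueError(f"invalid embedding: need 1 < L <= M, got L={L}, M={M}")
    X = hankel(v[:L], v[L - 1:])
    return Trajectory(X=X, L=L, fs=float(fs), start=start)


def decompose(tr: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the trajectory matrix, deterministically signed.

    Returns (singular_values, U, Vt) with singular values non-increasing and
    each EOF (column of U) oriented so its largest-magnitude entry is
    positive.
    """
    U, s, Vt = np.linalg.svd(tr.X, full_matrices=False)
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return s, U * flip, Vt * flip[:, None]


def elementary_matrix(s: np.ndarray, U: np.ndarray, Vt: np.ndarray, i: int) -> np.ndarray:
    """Rank-1 elementary matrix X_i = s_i U_i V_i^T."""
    return s[i] * np.outer(U[:, i], Vt[i])


def hankelize(Xi: np.ndarray) -> np.ndarray:
    """Diagonal averaging: z[t] = mean of entries on the anti-diagonal i+j = t.

    Maps an L x K matrix back to a series of length M = L + K - 1.  Computed
    with bincount over the flattened index sums, equivalent to the naive
    double loop.
    """
    L, K = Xi.shape
    idx = np.add.outer(np.arange(L), np.arange(K)).ravel()
    sums = np.bincount(idx, weights=Xi.ravel(), minlength=L + K - 1)
    counts = np.bincount(idx, minlength=L + K - 1)
    return sums / counts


def ssa_components(
    w: Window | TimeSeries,
    L: int = 17,
    n_keep: int = 3,
) -> SSAResult:
    """Full SSA pipeline: embed -> SVD -> Hankelize every elementary matrix.

    All ``d = min(L, M - L + 1)`` components are returned; the first
    ``n_keep`` are the ones used downstream for RR estimation.
    """
    tr = embed(w, L)
    s, U, Vt = decompose(tr)
    fs = tr.fs
    components = [
        TimeSeries(hankelize(elementary_matrix(s, U, Vt, i)), fs=fs, label=f"EOF{i + 1}")
        for i in range(s.size)
    ]
    return SSAResult(singular_values=s, eofs=U, components=components, n_keep=n_keep)


def rr_from_ssa(
    res: SSAResult,
    band,
    select: str = "power",
    window_index: int = -1,
    postprocess: bool = False,
):
    """Per-component respiratory rates and the combined SSA estimate.

    The first ``res.n_keep`` (default three) Hankelized components each
    yield an in-band spectral RR estimate; the combined ``RR_SSA`` value is
    the estimate whose peak carries the most power (``select="power"``) or
    the highest estimated frequency (``select="frequency"``).  With
    ``postprocess=True`` each component first passes through the
    artifact-reduction operator Pi.

    Returns ``(rr_ssa, per_eof)`` with labels RR_EOF1..; undefined
    estimates carry NaN.
    """
    from .signals import artifact_reduce
    from .spectral import RREstimate, rr_of_series

    if res.d < res.n_keep:
        raise ValueError(f"need at least {res.n_keep} components")
    per_eof: dict[str, RREstimate] = {}
    for i in range(res.n_keep):
        series = res.components[i]
        if postprocess:
            try:
                series = artifact_reduce(series)
            except ValueError:
                pass
        per_eof[f"RR_EOF{i + 1}"] = rr_of_series(
            series, band, estimator=f"RR_EOF{i + 1}", window_index=window_index
        )
    defined = [e for e in per_eof.values() if e.defined]
    if not defined:
        combined = RREstimate(float("nan"), "RR_SSA", window_index)
    else:
        key = (lambda e: e.peak_power) if select == "power" else (lambda e: e.value)
        best = max(defined, key=key)
        combined = RREstimate(best.value, "RR_SSA", window_index, best.peak_power)
    return combined, per_eof


def wcorr(res: SSAResult) -> np.ndarray:
    """Weighted-correlation matrix of the SSA components (diagnostic).

    Uses the standard SSA weights w[t] = number of anti-diagonal entries
    contributing to sample t, so that w-orthogonal components (e.g. a clean
    harmonic pair vs noise) show near-zero entries.
    """
    comps = np.vstack([c.values for c in res.components])
    M = comps.shape[1]
    L = res.eofs.shape[0]
    K = M - L + 1
    w = np.minimum(np.minimum(np.arange(1, M + 1), min(L, K)), M - np.arange(M))
    G = (comps * w) @ comps.T
    norms = np.sqrt(np.diag(G))
    norms[norms == 0] = 1.0
    return G / np.outer(norms, norms)
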