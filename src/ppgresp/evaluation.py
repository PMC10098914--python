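"""Estimator comparison: error metrics, agreement analysis, rank statistics.

Per-video RR estimates are compared with the reference through MAE and RMSE,
through Bland-Altman agreement analysis (bias, 1.96-sigma limits of
agreement, and a regression slope of differences on means exposing
proportional bias), and through a nonparametric multi-estimator protocol:

1. gate -- Shapiro-Wilk normality per estimator and Levene homogeneity across
   estimators; any normality rejection routes to the nonparametric branch;
2. omnibus -- Friedman test on the within-video ranks of the error metric;
3. post hoc -- Nemenyi pairwise comparisons via the Studentized range, with
   the critical difference CD = q_{alpha,k} / sqrt(2) * sqrt(k(k+1)/(6N))
   used for critical-difference diagrams;
4. effect size -- a robust standardized median difference (Akinshin's gamma):
   the difference of medians over the pooled MAD-based spread, labelled
   negligible / small / medium / large at |gamma| thresholds 0.2 / 0.5 / 0.8.

Ranks follow the critical-difference-diagram convention: estimators are
ranked within each video from best (rank 1 = smallest error) to worst, so a
LOWER average rank means a better estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedErrors",
    "BlandAltman",
    "GateReport",
    "RankComparison",
    "mae",
    "rmse",
    "bland_altman",
    "normality_gate",
    "friedman_nemenyi",
    "akinshin_gamma",
    "gamma_magnitude",
    "median_ci",
]

#: Consistency factor making the MAD estimate sigma for normal data.
_MAD_SCALE = 1.4826022185056018


@dataclass(frozen=True)
class PairedErrors:
    """Estimated vs reference RR (breaths/min), paired by video."""

    estimates: np.ndarray
    references: np.ndarray
    estimator: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.estimates, dtype=float)
        r = np.asarray(self.references, dtype=float)
        if e.shape != r.shape or e.ndim != 1:
            raise ValueError("estimates and references must be 1-D and paired")
        if e.size == 0:
            raise ValueError("empty input")
        object.__setattr__(self, "estimates", e)
        object.__setattr__(self, "references", r)

    @property
    def K(self) -> int:
        return self.estimates.size


def mae(pe: PairedErrors) -> float:
    """Mean absolute error, breaths/min."""
    return float(np.mean(np.abs(pe.estimates - pe.references)))


def rmse(pe: PairedErrors) -> float:
    """Root-mean-squared error, breaths/min."""
    return float(np.sqrt(np.mean((pe.estimates - pe.references) ** 2)))


@dataclass(frozen=True)
class BlandAltman:
    means: np.ndarray
    diffs: np.ndarray
    bias: float
    loa_lo: float
    loa_hi: float
    trend_slope: float
    trend_p: float


def bland_altman(pe: PairedErrors) -> BlandAltman:
    """Bland-Altman agreement: bias, limits of agreement, proportional-bias slope.

    The error convention is estimate minus reference, so a positive bias
    means the estimator overestimates RR on average.  The trend slope is the
    ordinary-least-squares slope of differences on means; a significant slope
    indicates rate-dependent (proportional) bias.  With degenerate variance
    in the means the slope is undefined and reported as NaN.
    """
    if pe.K < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    diffs = pe.estimates - pe.references
    means = 0.5 * (pe.estimates + pe.references)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if np.ptp(means) > 0:
        fit = stats.linregress(means, diffs)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    else:
        slope, slope_p = float("nan"), float("nan")
    return BlandAltman(
        means=means, diffs=diffs, bias=bias,
        loa_lo=bias - 1.96 * sd, loa_hi=bias + 1.96 * sd,
        trend_slope=slope, trend_p=slope_p,
    )


@dataclass(frozen=True)
class GateReport:
    shapiro_p: np.ndarray
    levene_p: float
    nonparametric: bool
    degenerate: np.ndarray


def normality_gate(populations: np.ndarray, alpha: float = 0.05) -> GateReport:
    """Shapiro-Wilk per column plus Levene across columns.

    ``populations`` is an (N videos x k estimators) matrix of an error
    metric.  Any per-column normality rejection (or a degenerate constant
    column) sets the nonparametric flag, routing the analysis to
    Friedman/Nemenyi instead of a parametric ANOVA.
    """
    pops = np.asarray(populations, dtype=float)
    if pops.ndim != 2 or pops.shape[1] < 2:
        raise ValueError("need an (N x k) matrix with k >= 2 estimators")
    k = pops.shape[1]
    shapiro_p = np.empty(k)
    degenerate = np.zeros(k, dtype=bool)
    for i in range(k):
        col = pops[:, i]
        if np.ptp(col) == 0:
            degenerate[i] = True
            shapiro_p[i] = 0.0
        else:
            shapiro_p[i] = stats.shapiro(col).pvalue
    valid = [pops[:, i] for i in range(k) if not degenerate[i]]
    levene_p = float(stats.levene(*valid).pvalue) if len(valid) >= 2 else float("nan")
    nonparam = bool(np.any(shapiro_p < alpha) or degenerate.any())
    return GateReport(shapiro_p=shapiro_p, levene_p=levene_p,
                      nonparametric=nonparam, degenerate=degenerate)


@dataclass(frozen=True)
class RankComparison:
    estimators: list[str]
    avg_ranks: np.ndarray
    friedman_stat: float
    friedman_p: float
    nemenyi_p: np.ndarray
    cd: float
    alpha: float


def _friedman_from_ranks(ranks: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with the midrank tie correction.

    Matches scipy.stats.friedmanchisquare; kept explicit so that the
    statistic is computable from an already-ranked matrix.
    """
    N, k = ranks.shape
    ssbn = float(np.sum(ranks.sum(axis=0) ** 2))
    chisq = (12.0 / (N * k * (k + 1))) * ssbn - 3 * N * (k + 1)
    # tie correction
    c = 1.0
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1 - ties / (N * (k**3 - k))
    if c > 0:
        chisq /= c
    p = float(stats.chi2.sf(chisq, k - 1))
    return float(chisq), p


def friedman_nemenyi(
    populations: np.ndarray,
    estimators: list[str] | None = None,
    alpha: float = 0.05,
) -> RankComparison:
    """Friedman omnibus test plus Nemenyi post hoc on an (N x k) error matrix.

    Lower error is better: errors are ranked within each video with midranks
    on ties, rank 1 = smallest error.  The Nemenyi pairwise p-value for
    estimators (i, j) is the Studentized-range tail of
    |R_i - R_j| / sqrt(k(k+1)/(12N)); the critical difference at ``alpha``
    is q_{alpha,k} / sqrt(2) * sqrt(k(k+1)/(6N)).
    """
    pops = np.asarray(populations, dtype=float)
    if pops.ndim != 2 or pops.shape[1] < 3:
        raise ValueError("Friedman needs at least 3 estimators (columns)")
    N, k = pops.shape
    if N < 2:
        raise ValueError("Friedman needs at least 2 paired samples")
    ranks = stats.rankdata(pops, axis=1)
    avg_ranks = ranks.mean(axis=0)
    stat, p = _friedman_from_ranks(ranks)

    se = np.sqrt(k * (k + 1) / (12.0 * N))
    q = np.abs(avg_ranks[:, None] - avg_ranks[None, :]) / se
    # Studentized range with infinite dof; sqrt(2) converts the pairwise
    # z-style statistic to the range scale
    nemenyi_p = stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf)
    nemenyi_p = np.clip(nemenyi_p, 0.0, 1.0)
    np.fill_diagonal(nemenyi_p, 1.0)

    q_alpha = float(stats.studentized_range.ppf(1 - alpha, k, np.inf))
    cd = q_alpha / np.sqrt(2.0) * np.sqrt(k * (k + 1) / (6.0 * N))
    names = estimators or [f"est{i + 1}" for i in range(k)]
    return RankComparison(
        estimators=list(names), avg_ranks=avg_ranks,
        friedman_stat=stat, friedman_p=p,
        nemenyi_p=nemenyi_p, cd=cd, alpha=alpha,
    )


def gamma_magnitude(gamma: float) -> str:
    """Label |gamma| as negligible (<0.2), small (<0.5), medium (<0.8) or large."""
    g = abs(gamma)
    if not np.isfinite(g):
        return "undefined"
    if g < 0.2:
        return "negligible"
    if g < 0.5:
        return "small"
    if g < 0.8:
        return "medium"
    return "large"


def akinshin_gamma(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Robust standardized median difference between two samples.

    gamma = (median(b) - median(a)) / pooled spread, where each sample's
    spread is its median absolute deviation scaled to be consistent with the
    standard deviation under normality, pooled as a variance-weighted
    average.  Returns the value together with its magnitude label.  A zero
    pooled spread leaves gamma undefined (NaN, "undefined").
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValueError("both samples need at least 10 observations")
    s_a = _MAD_SCALE * np.median(np.abs(a - np.median(a)))
    s_b = _MAD_SCALE * np.median(np.abs(b - np.median(b)))
    pooled = np.sqrt(((a.size - 1) * s_a**2 + (b.size - 1) * s_b**2)
                     / (a.size + b.size - 2))
    if pooled == 0:
        if np.median(b) == np.median(a):
            return 0.0, "negligible"
        return float("nan"), "undefined"
    g = float((np.median(b) - np.median(a)) / pooled)
    return g, gamma_magnitude(g)


def median_ci(
    sample: np.ndarray,
    confidence: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Sample median with a seeded bootstrap percentile confidence interval."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    rng = np.random.default_rng(seed)
    boots = np.median(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
    lo_q = (1 - confidence) / 2
    lo, hi = np.quantile(boots, [lo_q, 1 - lo_q])
    return med, (float(lo), float(hi))
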