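"""Parameter estimation for the kinetic model.

Everything fitted here is linear: the through-origin slope of N/S versus
octamer concentration Q (the composite rate kbar*(alpha + eps*T) at one
dialysis time), the ordinary regression of those slopes on dialysis time T
(separating the composites kbar*alpha and kbar*eps), the zero-intercept
competition-ratio fit of N_A/N_Z on Q_A/Q_Z (estimating kbar_A/kbar_Z), and
a replicate-slope comparison across DNA templates (affinity ranking with
permutation p-values). Through-origin fits use the closed form
slope = Σxy / Σx², with the (0, 0) anchor appended when absent, matching
how the gel experiments are analysed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "SlopeFit",
    "TimeTrend",
    "RatioFit",
    "AffinityComparison",
    "fit_efficiency_slope",
    "fit_slope_vs_time",
    "fit_competition_ratio",
    "through_origin_slope",
    "permutation_pvalue",
    "compare_affinity",
]

#: Permutation-test resampling budget: exhaustive when the number of
#: distinct label assignments is at most this, else Monte-Carlo with 10^4.
EXHAUSTIVE_LIMIT = 20_000
MC_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class SlopeFit:
    """Through-origin least-squares slope with uncertainty."""

    slope: float
    stderr: float
    r_squared: float
    n: int
    unit: str = "per ug/mL"


@dataclass(frozen=True)
class TimeTrend:
    """OLS of per-time slopes on dialysis time: slope(T) = intercept + rate*T.

    ``intercept`` estimates the composite kbar*alpha (per concentration
    unit) and ``rate`` the composite kbar*eps (per concentration unit per
    hour); alpha and eps are not separately identifiable.
    """

    intercept: float
    rate: float
    r_squared: float
    times: tuple[float, ...]
    slopes: tuple[float, ...]


@dataclass(frozen=True)
class RatioFit:
    """Zero-intercept estimate of kbar_A/kbar_Z from competition data."""

    ratio: float
    stderr: float
    n: int


@dataclass(frozen=True)
class AffinityComparison:
    """Template ranking by mean replicate slope, with pairwise p-values."""

    ranking: tuple[str, ...]          # templates, highest mean slope first
    mean_slopes: dict[str, float]
    pvalues: dict[tuple[str, str], float] | None   # None if single replicates


def through_origin_slope(x: np.ndarray, y: np.ndarray, unit: str = "") -> SlopeFit:
    """Least squares with the intercept fixed at zero: slope = Σxy / Σx².

    The standard error is the regression-through-origin form
    sqrt(RSS / (n - 1) / Σx²); R² is computed about zero (uncentered), the
    appropriate definition for a no-intercept model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired observations")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all x are zero; slope undefined")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    dof = x.size - 1
    stderr = math.sqrt(float(np.sum(resid**2)) / dof / sxx) if dof > 0 else float("nan")
    tss = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else float("nan")
    return SlopeFit(slope=slope, stderr=stderr, r_squared=r2, n=int(x.size), unit=unit)


def fit_efficiency_slope(
    Q: np.ndarray | list[float],
    efficiency: np.ndarray | list[float],
    unit: str = "per ug/mL",
) -> SlopeFit:
    """Through-origin slope of N/S versus octamer concentration Q.

    Replicates enter as individual points (no pre-averaging). The (0, 0)
    anchor — zero assembly at zero octamer — is appended as a single point
    if no Q = 0 observation is present, mirroring the gel analysis.
    """
    q = np.asarray(Q, dtype=float)
    y = np.asarray(efficiency, dtype=float)
    if q.size != y.size or q.size == 0:
        raise ValueError("Q and efficiency must be equal-length and non-empty")
    if np.unique(q[q >= 0]).size < 2 and not np.any(q == 0):
        raise ValueError("need >= 2 distinct Q values")
    if not np.any(q == 0.0):
        q = np.append(q, 0.0)
        y = np.append(y, 0.0)
    if np.all(q == 0.0):
        raise ValueError("all Q are zero")
    return through_origin_slope(q, y, unit=unit)


def fit_slope_vs_time(
    times: np.ndarray | list[float],
    slopes: np.ndarray | list[float],
) -> TimeTrend:
    """Ordinary least squares (free intercept) of per-time slopes on T."""
    t = np.asarray(times, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if t.size != s.size or t.size < 2:
        raise ValueError("need >= 2 (time, slope) pairs")
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct times")
    rate, intercept = np.polyfit(t, s, 1)
    fitted = intercept + rate * t
    ss_res = float(np.sum((s - fitted) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TimeTrend(
        intercept=float(intercept), rate=float(rate), r_squared=r2,
        times=tuple(float(v) for v in t), slopes=tuple(float(v) for v in s),
    )


def fit_competition_ratio(
    qa_over_qz: np.ndarray | list[float],
    na_over_nz: np.ndarray | list[float],
) -> RatioFit:
    """Zero-intercept fit of N_A/N_Z on Q_A/Q_Z: the kbar_A/kbar_Z estimate.

    Non-finite pairs (flagged endpoint gradients, zero-denominator blots)
    are dropped; at least 2 usable gradients are required.
    """
    x = np.asarray(qa_over_qz, dtype=float)
    y = np.asarray(na_over_nz, dtype=float)
    if x.size != y.size:
        raise ValueError("mismatched lengths")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError(f"need >= 2 usable gradients, got {x.size}")
    fit = through_origin_slope(x, y)
    return RatioFit(ratio=fit.slope, stderr=fit.stderr, n=fit.n)


def permutation_pvalue(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    seed: int | None = None,
) -> float:
    """Two-sided permutation test on the difference of means of two samples.

    Exhaustive over all label assignments when their count is at most
    ``EXHAUSTIVE_LIMIT``; otherwise ``MC_PERMUTATIONS`` seeded resamples
    (the observed assignment is always counted, so p > 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = a.size
    observed = abs(a.mean() - b.mean())
    n_total = pooled.size
    n_comb = math.comb(n_total, na)
    if n_comb <= EXHAUSTIVE_LIMIT:
        count = 0
        idx_all = np.arange(n_total)
        total_sum = pooled.sum()
        for comb in combinations(idx_all, na):
            sa = pooled[list(comb)].sum()
            stat = abs(sa / na - (total_sum - sa) / (n_total - na))
            if stat >= observed - 1e-12 * max(1.0, observed):
                count += 1
        return count / n_comb
    rng = np.random.default_rng(seed)
    count = 1  # the observed assignment
    total_sum = pooled.sum()
    for _ in range(MC_PERMUTATIONS):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].mean() - perm[na:].mean())
        if stat >= observed - 1e-12 * max(1.0, observed):
            count += 1
    return count / (MC_PERMUTATIONS + 1)


def compare_affinity(
    replicate_slopes: dict[str, np.ndarray | list[float]],
    seed: int | None = None,
) -> AffinityComparison:
    """Rank DNA templates by mean assembly slope; pairwise permutation tests.

    The through-origin slope of each template's gradient is a composite of
    its kbar, so comparing replicate slopes compares template-octamer
    affinities. With a single replicate per template only the ranking is
    returned (p-values withheld).
    """
    if len(replicate_slopes) < 2:
        raise ValueError("need >= 2 templates to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in replicate_slopes.items()}
    means = {k: float(v.mean()) for k, v in arrays.items()}
    ranking = tuple(sorted(means, key=means.get, reverse=True))
    if any(v.size < 2 for v in arrays.values()):
        return AffinityComparison(ranking=ranking, mean_slopes=means, pvalues=None)
    pvalues: dict[tuple[str, str], float] = {}
    for i, ta in enumerate(ranking):
        for tb in ranking[i + 1:]:
            pvalues[(ta, tb)] = permutation_pvalue(arrays[ta], arrays[tb], seed=seed)
    return AffinityComparison(ranking=ranking, mean_slopes=means, pvalues=pvalues)
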