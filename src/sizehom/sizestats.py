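"""Dispersion statistics and inference for cell-length distributions.

The relative dispersion of cell length at division is the screen's central
quantity. Two scale-free measures are used:

* ``CV = 100 * SD / mean`` (sample SD, n-1 denominator), sensitive to
  outliers such as spontaneous diploids;
* ``CQV = 100 * (Q3 - Q1) / (Q3 + Q1)``, an outlier-robust quartile
  analogue (quartiles by linear interpolation of order statistics,
  ``h = (n - 1) p + 1``).

Equality of CVs across groups is tested with the Feltz-Miller asymptotic
chi-square statistic: with per-group CV fractions ``c_i = s_i / xbar_i``,
weights ``m_i = n_i - 1`` and pooled ``cbar = sum(m_i c_i) / sum(m_i)``,

    D_AD = sum(m_i (c_i - cbar)^2) / (cbar^2 (0.5 + cbar^2))

is asymptotically chi-square with k-1 degrees of freedom under the null of a
common CV. A permutation version (group labels permuted after scaling each
group to unit mean) serves as a small-sample cross-check.

Sample-size support: the chi-square confidence interval for a normal SD gives
multiplicative CI factors for sigma, and the smallest n whose factors deviate
from 1 by at most a requested relative half-width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SizeSummary",
    "CVTestResult",
    "coefficient_of_variation",
    "coefficient_of_quartile_variation",
    "sample_skewness",
    "size_summary",
    "cv_equality_test",
    "cv_equality_permutation",
    "sd_ci_factors",
    "min_sample_size",
]


@dataclass
class SizeSummary:
    """Descriptive statistics of one strain's division lengths (µm)."""

    strain: str
    n: int
    mean: float
    sd: float
    cv: float  # percent
    cqv: float  # percent
    skewness: float
    q1: float
    median: float
    q3: float
    min: float
    max: float


@dataclass
class CVTestResult:
    """Feltz-Miller asymptotic test for equality of coefficients of variation.

    ``cvs`` are CV fractions (not percent); ``weights`` are ``n_i - 1``.
    """

    labels: tuple
    cvs: tuple
    weights: tuple
    pooled_cv: float
    statistic: float
    df: int
    p_value: float


def _as_array(values, min_n: int, name: str = "values") -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {x.size}")
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")
    return x


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: 100 * sample SD (n-1) / mean. Requires n >= 2, mean > 0."""
    x = _as_array(values, 2)
    mean = x.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return 100.0 * x.std(ddof=1) / mean


def coefficient_of_quartile_variation(values: Sequence[float]) -> float:
    """CQV in percent: 100 * (Q3 - Q1) / (Q3 + Q1).

    Quartiles use linear interpolation of order statistics
    (``h = (n - 1) p + 1``). Requires n >= 4 and Q1 + Q3 > 0.
    """
    x = _as_array(values, 4)
    q1, q3 = np.percentile(x, [25.0, 75.0], method="linear")
    if q1 + q3 <= 0:
        raise ValueError("CQV requires Q1 + Q3 > 0")
    return 100.0 * (q3 - q1) / (q3 + q1)


def sample_skewness(values: Sequence[float]) -> float:
    """Moment-ratio skewness g1 = m3 / m2^(3/2) with 1/n central moments.

    The plain (biased) estimator; the screen's symmetry gate (|g1| <= 1) is
    insensitive to the finite-sample correction at the n >= 50 it is applied
    to.
    """
    x = _as_array(values, 3)
    if x.std(ddof=0) == 0:
        raise ValueError("skewness undefined for zero-variance data")
    return float(stats.skew(x, bias=True))


def size_summary(values: Sequence[float], strain: str = "") -> SizeSummary:
    """Full descriptive summary of one strain's division lengths."""
    x = _as_array(values, 2)
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0], method="linear")
    sd = x.std(ddof=1)
    mean = x.mean()
    return SizeSummary(
        strain=strain,
        n=int(x.size),
        mean=float(mean),
        sd=float(sd),
        cv=coefficient_of_variation(x),
        cqv=coefficient_of_quartile_variation(x) if x.size >= 4 else float("nan"),
        skewness=sample_skewness(x) if x.size >= 3 and sd > 0 else float("nan"),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        min=float(x.min()),
        max=float(x.max()),
    )


def _group_cvs(groups) -> tuple[np.ndarray, np.ndarray]:
    cvs, weights = [], []
    for i, g in enumerate(groups):
        x = _as_array(g, 2, name=f"group {i}")
        mean = x.mean()
        if mean <= 0:
            raise ValueError(f"group {i} has non-positive mean")
        cvs.append(x.std(ddof=1) / mean)
        weights.append(x.size - 1)
    return np.asarray(cvs), np.asarray(weights, dtype=float)


def _feltz_miller(cvs: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    pooled = float(np.sum(weights * cvs) / np.sum(weights))
    if pooled == 0:
        raise ValueError("pooled CV is zero; test undefined")
    stat = float(
        np.sum(weights * (cvs - pooled) ** 2) / (pooled**2 * (0.5 + pooled**2))
    )
    return stat, pooled


def cv_equality_test(
    groups: Sequence[Sequence[float]], labels: Sequence | None = None
) -> CVTestResult:
    """Feltz-Miller asymptotic chi-square test of CV equality across groups.

    Parameters
    ----------
    groups : sequence of samples
        Two or more samples of positive-mean measurements (each n >= 2).
    labels : optional sequence of group labels.

    Returns
    -------
    CVTestResult
        Statistic ``D_AD``, degrees of freedom ``k - 1`` and upper-tail
        chi-square p-value. The statistic is invariant to rescaling any
        single group by a positive constant.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("cv_equality_test needs at least 2 groups")
    if labels is None:
        labels = tuple(range(len(groups)))
    cvs, weights = _group_cvs(groups)
    stat, pooled = _feltz_miller(cvs, weights)
    df = len(groups) - 1
    p = float(stats.chi2.sf(stat, df))
    return CVTestResult(
        labels=tuple(labels),
        cvs=tuple(float(c) for c in cvs),
        weights=tuple(float(w) for w in weights),
        pooled_cv=pooled,
        statistic=stat,
        df=df,
        p_value=p,
    )


def cv_equality_permutation(
    groups: Sequence[Sequence[float]],
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Permutation p-value for CV equality (oracle for the asymptotic test).

    Each group is scaled to unit mean (removing location/scale information so
    only relative dispersion is exchangeable), scaled values are pooled, group
    labels are permuted ``n_perm`` times and the Feltz-Miller statistic is
    recomputed. Returns the add-one-corrected p-value
    ``(b + 1) / (n_perm + 1)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("cv_equality_permutation needs at least 2 groups")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = cv_equality_test(groups).statistic
    scaled = [g / g.mean() for g in groups]
    pooled = np.concatenate(scaled)
    sizes = [g.size for g in groups]
    edges = np.cumsum(sizes)[:-1]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, edges)
        cvs, weights = _group_cvs(parts)
        stat, _ = _feltz_miller(cvs, weights)
        if stat >= observed:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def sd_ci_factors(n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Multiplicative chi-square CI factors for a normal SD.

    Given a sample SD ``s`` from ``n`` observations, the confidence interval
    for sigma is ``(low * s, high * s)`` with

        low  = sqrt((n-1) / chi2_{(1+conf)/2, n-1})
        high = sqrt((n-1) / chi2_{(1-conf)/2, n-1})
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    alpha = (1.0 - confidence) / 2.0
    low = float(np.sqrt((n - 1) / stats.chi2.ppf(1.0 - alpha, n - 1)))
    high = float(np.sqrt((n - 1) / stats.chi2.ppf(alpha, n - 1)))
    return low, high


def min_sample_size(
    relative_halfwidth: float, confidence: float = 0.95, max_n: int = 10**6
) -> int:
    """Smallest n whose SD CI factors deviate from 1 by at most ``r``.

    Finds the smallest ``n`` with
    ``max(1 - low_factor(n), high_factor(n) - 1) <= relative_halfwidth``;
    the returned n satisfies the criterion and n-1 violates it.
    """
    r = relative_halfwidth
    if not 0.0 < r < 1.0:
        raise ValueError("relative_halfwidth must be in (0, 1)")
    for n in range(2, max_n + 1):
        low, high = sd_ci_factors(n, confidence)
        if max(1.0 - low, high - 1.0) <= r:
            return n
    raise RuntimeError(
        f"no n <= {max_n} achieves relative halfwidth {r}; request is too strict"
    )
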