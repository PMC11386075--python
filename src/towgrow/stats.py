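"""Self-contained implementations of the study's named univariate statistics.

The four procedures here — the Welch–Satterthwaite two-sample *t* test,
Spearman rank correlation, the Kruskal–Wallis test, and Benjamini–Hochberg
false-discovery-rate adjustment — are the statistics the dust-incubation
analysis relies on for concentration comparisons, moisture–growth
association, alpha-diversity significance, and differential-abundance
multiplicity control. They are implemented from their defining formulas;
only the reference t and chi-square distribution functions come from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _spdist

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "TestResult",
    "welch_t",
    "spearman",
    "kruskal_wallis",
    "bh_fdr",
    "midranks",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is test-specific (t, rho, or H); ``df`` may be fractional
    (Satterthwaite); ``p_value`` is two-sided unless the test is one-sided by
    construction (Kruskal–Wallis). ``flags`` records degenerate-input notes.
    """

    statistic: float
    df: float
    p_value: float
    flags: tuple[str, ...] = field(default=())


def _as_clean_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def welch_t(x, y) -> TestResult:
    """Two-sample t test with the Satterthwaite degrees-of-freedom
    approximation (unequal variances, two-sided).

    t = (x̄ − ȳ) / sqrt(s²x/n + s²y/m), with

    df = (s²x/n + s²y/m)² / [ (s²x/n)²/(n−1) + (s²y/m)²/(m−1) ].
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise InsufficientDataError("welch_t requires at least 2 values per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / n + vy / m
    if se2 == 0.0:
        # both samples constant; equal means -> no evidence either way
        flags = ("zero-variance",)
        return TestResult(statistic=0.0, df=float(n + m - 2), p_value=1.0, flags=flags)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1))
    p = 2.0 * _spdist.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(min(p, 1.0)))


def midranks(values) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of the spanned ranks."""
    arr = np.asarray(values, dtype=float).ravel()
    order = np.argsort(arr, kind="mergesort")
    ranks = np.empty(arr.size, dtype=float)
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and arr[order[j + 1]] == arr[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value by full enumeration (small n only)."""
    n = rx.size
    denom = math.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
    count = 0
    total = 0
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    for perm in itertools.permutations(range(n)):
        rho = float(np.dot(rx_c[list(perm)], ry_c)) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y, exact: bool = False) -> TestResult:
    """Spearman rank correlation (average ranks for ties).

    The p-value uses the t approximation t = rho·sqrt((n−2)/(1−rho²)); with
    ``exact=True`` and n ≤ 9 a full permutation p-value is computed instead.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("spearman requires n >= 3")
    rx = midranks(x)
    ry = midranks(y)
    sx = rx.std(ddof=0)
    sy = ry.std(ddof=0)
    if sx == 0.0 or sy == 0.0:
        return TestResult(statistic=float("nan"), df=float(n - 2), p_value=1.0,
                          flags=("constant-input",))
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(abs(rho) - 1.0) < 1e-12:
        rho = math.copysign(1.0, rho)  # snap exact concordance/discordance
    if exact:
        if n > 9:
            raise ValidationError("exact permutation p available only for n <= 9")
        p = _exact_spearman_p(rx, ry, rho)
        return TestResult(statistic=rho, df=float(n - 2), p_value=float(p))
    if abs(rho) == 1.0:
        return TestResult(statistic=rho, df=float(n - 2), p_value=0.0)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * _spdist.t.sf(abs(t), n - 2)
    return TestResult(statistic=rho, df=float(n - 2), p_value=float(min(p, 1.0)))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis rank test for a ≥ 2 groups with tie correction.

    H = [12/(N(N+1)) · Σ n_i (R̄_i − R̄)²] / [1 − Σ(t³−t)/(N³−N)],
    referred to chi-square with a − 1 degrees of freedom.
    """
    arrays = [_as_clean_array(g, "group") for g in groups]
    a = len(arrays)
    if a < 2:
        raise ValidationError("kruskal_wallis requires at least 2 groups")
    if any(g.size == 0 for g in arrays):
        raise ValidationError("kruskal_wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise InsufficientDataError("kruskal_wallis requires total n >= 3")
    ranks = midranks(pooled)
    rbar = (n_total + 1) / 2.0
    h = 0.0
    start = 0
    for g in arrays:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - rbar) ** 2
        start += g.size
    h *= 12.0 / (n_total * (n_total + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    denom = 1.0 - tie_sum / (n_total**3 - n_total)
    if denom == 0.0:
        return TestResult(statistic=0.0, df=float(a - 1), p_value=1.0,
                          flags=("all-identical",))
    h /= denom
    p = _spdist.chi2.sf(h, a - 1)
    return TestResult(statistic=float(h), df=float(a - 1), p_value=float(p))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input.

    q_(i) = min_{j >= i} p_(j) · m / j over the ascending-sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q
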