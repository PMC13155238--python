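"""Sample-size- and coverage-standardised diversity of record-count assemblages.

Implements Good's coverage, Hill numbers of orders 0/1/2, exact hypergeometric
rarefaction (interpolation only — never extrapolation), the Good-Turing
adjusted coverage estimator for interpolated samples, coverage-based
standardisation at a target coverage C*, evenness summaries, and multinomial
bootstrap intervals.

Hill numbers give the effective number of species at order q: q=0 is richness,
q=1 the exponential of Shannon entropy (natural log), q=2 the inverse Simpson
concentration.  Rarefied q=1 and q=2 are computed from the expected
abundance-frequency counts under hypergeometric subsampling, which is how the
standard interpolation formulas are constructed; a Monte-Carlo subsampling
oracle validates them in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "AbundanceVector",
    "goods_coverage",
    "hill_number",
    "rarefy_hill",
    "coverage_at_m",
    "standardise_by_coverage",
    "evenness_suite",
    "bootstrap_hill",
    "HillEstimate",
]


@dataclass
class AbundanceVector:
    """A taxon-count vector with its singleton/doubleton summaries."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or (c <= 0).any():
            raise ValueError("counts must be a 1-d vector of positive integers")
        self.counts = c

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def f1(self) -> int:
        return int((self.counts == 1).sum())

    @property
    def f2(self) -> int:
        return int((self.counts == 2).sum())


def _as_counts(v) -> np.ndarray:
    if isinstance(v, AbundanceVector):
        return v.counts
    c = np.asarray(v, dtype=np.int64)
    return c[c > 0]


def goods_coverage(n: int, f1: int) -> float:
    """Good's coverage, 1 - singletons/total records.

    The plain Good form used for descriptive stratum summaries.  Undefined
    (NaN) for an empty stratum.
    """
    if n == 0:
        return float("nan")
    if not 0 <= f1 <= n:
        raise ValueError("need 0 <= f1 <= n")
    return 1.0 - f1 / n


def hill_number(v, q: int) -> float:
    """Observed Hill number of order q in {0, 1, 2}."""
    c = _as_counts(v)
    if c.size == 0:
        raise ValueError("empty abundance vector")
    p = c / c.sum()
    if q == 0:
        return float(c.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2:
        return float(1.0 / np.sum(p**2))
    raise ValueError("q must be 0, 1 or 2")


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def _expected_freq_counts(counts: np.ndarray, m: int) -> np.ndarray:
    """E[f_k(m)] for k = 0..m under hypergeometric subsampling without
    replacement: E[f_k] = sum_i C(x_i, k) C(n - x_i, m - k) / C(n, m)."""
    n = counts.sum()
    k = np.arange(m + 1)
    log_cnm = _log_choose(n, m)
    # matrix over species x k
    logs = (
        _log_choose(counts[:, None], k[None, :])
        + _log_choose(n - counts[:, None], m - k[None, :])
        - log_cnm
    )
    return np.exp(logs).sum(axis=0)


def rarefy_hill(v, m: int, q: int) -> float:
    """Expected Hill number of order q in a subsample of size m (interpolation).

    q=0 uses the exact hypergeometric expectation
    S - sum_i C(n - x_i, m) / C(n, m); q=1 is exp of the entropy of the
    expected frequency counts; q=2 has the closed form
    1 / (1/m + (1 - 1/m) * sum_i x_i (x_i - 1) / (n (n - 1))).
    m = n returns the observed value; m > n raises (no extrapolation).
    """
    c = _as_counts(v)
    n = int(c.sum())
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}]; extrapolation is not supported")
    if m == n:
        return hill_number(c, q)
    if q == 0:
        log_cnm = _log_choose(n, m)
        miss = np.exp(_log_choose(n - c, m) - log_cnm)
        return float(c.size - miss.sum())
    if q == 1:
        ef = _expected_freq_counts(c, m)
        k = np.arange(m + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(k > 0, -(k / m) * np.log(k / m), 0.0)
        h = float(np.sum(term * ef))
        return float(np.exp(h))
    if q == 2:
        if n == 1:
            return 1.0
        c2 = float(np.sum(c * (c - 1)) / (n * (n - 1)))
        return float(1.0 / (1.0 / m + (1.0 - 1.0 / m) * c2))
    raise ValueError("q must be 0, 1 or 2")


def coverage_at_m(v, m: int) -> float:
    """Estimated sample coverage of an interpolated sample of size m.

    For m < n the expected-coverage estimator
    C(m) = 1 - sum_i (x_i/n) C(n - x_i, m) / C(n - 1, m); at m = n the
    Good-Turing f1/f2-adjusted form
    C(n) = 1 - (f1/n) * ((n-1) f1 / ((n-1) f1 + 2 f2)).
    """
    c = _as_counts(v)
    n = int(c.sum())
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}]")
    if m < n:
        log_d = _log_choose(n - c, m) - _log_choose(n - 1, m)
        return float(1.0 - np.sum((c / n) * np.exp(log_d)))
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f1 == 0:
        return 1.0
    adj = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    return float(1.0 - (f1 / n) * adj)


@dataclass
class HillEstimate:
    """A (possibly standardised) Hill-number estimate with bootstrap bounds."""

    q: int
    point: float
    lower: float
    upper: float
    n_boot: int
    m: int | None = None
    coverage_target: float | None = None
    coverage_reached: float | None = None
    warning: str | None = None


def bootstrap_hill(
    v,
    statistic,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile 95% bootstrap interval for a statistic of a count vector.

    Resamples n individuals multinomially from the empirical proportions
    (200 replicates by default).
    """
    rng = rng or np.random.default_rng(0)
    c = _as_counts(v)
    n = int(c.sum())
    p = c / n
    reps = []
    for _ in range(n_boot):
        draw = rng.multinomial(n, p)
        draw = draw[draw > 0]
        if draw.size == 0:
            continue
        reps.append(statistic(draw))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def smallest_m_for_coverage(v, c_star: float) -> tuple[int, bool]:
    """Smallest subsample size m with estimated coverage >= c_star.

    Returns (m, reached).  Coverage is non-decreasing in m, so a bisection
    over [1, n] suffices; if even m = n falls short, (n, False) is returned.
    """
    c = _as_counts(v)
    n = int(c.sum())
    if c_star <= 0:
        return 1, True
    if coverage_at_m(c, n) < c_star:
        return n, False
    lo, hi = 1, n
    while lo < hi:
        mid = (lo + hi) // 2
        if coverage_at_m(c, mid) >= c_star:
            hi = mid
        else:
            lo = mid + 1
    return lo, True


def standardise_by_coverage(
    v,
    c_star: float,
    q: int,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> HillEstimate:
    """Hill number standardised to a common target coverage C*.

    Finds the smallest interpolated sample size whose estimated coverage
    reaches C*, evaluates the Hill number there, and attaches a percentile
    bootstrap interval (the m-selection is repeated inside each replicate).
    If C* is unreachable by interpolation the boundary m = n estimate is
    returned with a warning flag.
    """
    rng = rng or np.random.default_rng(0)
    c = _as_counts(v)
    m, reached = smallest_m_for_coverage(c, c_star)
    point = rarefy_hill(c, m, q)

    def stat(draw):
        mm, _ = smallest_m_for_coverage(draw, c_star)
        return rarefy_hill(draw, mm, q)

    lo, hi = bootstrap_hill(c, stat, n_boot=n_boot, rng=rng)
    lo, hi = min(lo, point), max(hi, point)
    return HillEstimate(
        q=q,
        point=point,
        lower=lo,
        upper=hi,
        n_boot=n_boot,
        m=m,
        coverage_target=c_star,
        coverage_reached=coverage_at_m(c, m),
        warning=None if reached else "target coverage unreachable by interpolation",
    )


def evenness_suite(v) -> dict[str, float]:
    """Pielou's J (= q1D/q0D), Shannon H' (natural log) and Gini-Simpson 1-D."""
    c = _as_counts(v)
    q0 = hill_number(c, 0)
    q1 = hill_number(c, 1)
    p = c / c.sum()
    return {
        "pielou_J": q1 / q0,
        "shannon_H": float(-np.sum(p * np.log(p))),
        "gini_simpson": float(1.0 - np.sum(p**2)),
    }
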