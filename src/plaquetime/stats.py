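"""Shared statistical primitives.

Thin, explicit versions of the tests used across the pipeline: Pearson
correlation with the exact t reference distribution, Benjamini-Hochberg
step-up adjustment, one-sided Fisher's exact test, paired t, and the
noncentral-t power analysis used to size validation cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PowerSpec",
    "pearson",
    "bh_adjust",
    "fisher_exact_greater",
    "min_n_power",
    "power_one_sample",
    "paired_t",
]


@dataclass(frozen=True)
class PowerSpec:
    """Target for a minimum-sample-size computation.

    ``d`` is the standardized effect size (Cohen's d); ``test`` selects
    the family — the one-sample one-sided t is the default configuration
    consistent with printed minima of n=3 (d=2.5) and n=5 (d=1.5) at
    alpha=0.05, power 0.8.
    """

    effect_size: float
    alpha: float = 0.05
    target_power: float = 0.8
    test: str = "one_sample_one_sided"

    def __post_init__(self):
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must be in (0, 1)")
        if self.test not in ("one_sample_one_sided", "one_sample_two_sided",
                             "two_sample"):
            raise ValueError(f"unknown test family {self.test!r}")


def pearson(x, y) -> tuple[float, float]:
    """Product-moment r with two-sided p from t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher's exact p: hypergeometric upper tail at a."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    # margins: draws = a+b (in list), successes in population = a+c, N total
    N = a + b + c + d
    return float(sstats.hypergeom.sf(a - 1, N, a + c, a + b))


def power_one_sample(n: int, d: float, alpha: float,
                     two_sided: bool = False) -> float:
    """Exact power of the one-sample t test via the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = d * np.sqrt(n)
    if two_sided:
        tcrit = sstats.t.ppf(1 - alpha / 2, df)
        return float(sstats.nct.sf(tcrit, df, nc) + sstats.nct.cdf(-tcrit, df, nc))
    tcrit = sstats.t.ppf(1 - alpha, df)
    return float(sstats.nct.sf(tcrit, df, nc))


def _power_two_sample(n: int, d: float, alpha: float) -> float:
    """Two-sided two-sample t power, equal group sizes n."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    tcrit = sstats.t.ppf(1 - alpha / 2, df)
    return float(sstats.nct.sf(tcrit, df, nc) + sstats.nct.cdf(-tcrit, df, nc))


def min_n_power(spec: PowerSpec, n_max: int = 10 ** 6) -> int:
    """Smallest n with power >= target, by increment from n = 2."""
    for n in range(2, n_max + 1):
        if spec.test == "one_sample_one_sided":
            pw = power_one_sample(n, spec.effect_size, spec.alpha, False)
        elif spec.test == "one_sample_two_sided":
            pw = power_one_sample(n, spec.effect_size, spec.alpha, True)
        else:
            pw = _power_two_sample(n, spec.effect_size, spec.alpha)
        if pw >= spec.target_power:
            return n
    raise ValueError(f"target power not reachable within n <= {n_max}")


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t test on the per-pair differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length inputs with n >= 2")
    diff = x - y
    if np.std(diff, ddof=1) == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = sstats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
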