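"""Statistical procedures used throughout the reports.

Equal-variance two-tailed t-tests (pooled variance, df = n_a + n_b - 2),
the standard error of the mean, exact binomial tail probabilities
(two-sided by doubling the smaller tail, capped at 1 - the spreadsheet
convention), and dwell-length histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "t_test_equal_variance",
    "sem",
    "binomial_tail_p",
    "lifetime_histogram",
]


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class despite the name

    statistic: float
    p_value: float
    df: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def t_test_equal_variance(sample_a, sample_b) -> TestResult:
    """Two-tailed pooled-variance (Student) t-test.

    Degenerate inputs follow fixed conventions: zero pooled variance with
    equal means gives p = 1, with unequal means p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    na, nb = a.size, b.size
    df = na + nb - 2
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df
    diff = a.mean() - b.mean()
    method = "two-tailed equal-variance t-test"
    if pooled == 0.0:
        if diff == 0.0:
            return TestResult(statistic=0.0, p_value=1.0, df=df, method=method)
        return TestResult(
            statistic=float(np.sign(diff) * np.inf), p_value=0.0, df=df,
            method=method + " (zero variance, unequal means)",
        )
    t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=float(min(p, 1.0)), df=df,
                      method=method)


def sem(values) -> float:
    """Standard error of the mean: sd (n-1 denominator) / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM needs at least two observations")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def binomial_tail_p(k: int, n: int, p0: float, tail: str = "two") -> float:
    """Exact binomial tail probability for k successes in n trials at p0.

    ``tail="ge"`` is P(X >= k), ``"le"`` is P(X <= k); ``"two"`` doubles
    the smaller of the two, capped at 1.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    dist = sps.binom(n, p0)
    p_le = float(dist.cdf(k))
    p_ge = float(dist.sf(k - 1))
    if tail == "ge":
        return p_ge
    if tail == "le":
        return p_le
    if tail == "two":
        return min(1.0, 2.0 * min(p_le, p_ge))
    raise ValueError(f"unknown tail {tail!r}")


def lifetime_histogram(lengths, max_length: int | None = None) -> dict[int, int]:
    """Counts of dwell events per exact run length.

    Lengths above ``max_length`` (if given) are pooled into an overflow
    bin keyed by ``max_length + 1``.
    """
    out: dict[int, int] = {}
    for length in lengths:
        length = int(length)
        if length < 1:
            raise ValueError("event lengths must be >= 1")
        key = length if max_length is None or length <= max_length else max_length + 1
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items()))
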