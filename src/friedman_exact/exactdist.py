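"""Exact null distribution of the Friedman rank-sum difference.

Under the Friedman null hypothesis every within-block permutation of the
ranks 1..k is equally likely, independently across the n blocks.  For a
fixed pair of groups the per-block difference of their ranks takes the
values t = -(k-1), ..., -1, 1, ..., k-1 with multiplicity k - |t| (out of
k(k-1) ordered rank pairs), and the total difference D = R_i - R_j is the
n-fold sum of independent copies of that per-block difference.  Its support
is the integer interval [-n(k-1), n(k-1)] and its distribution is symmetric
about zero.

This module computes the composition counts W(D = d; k, n), point
probabilities, one- and two-sided tail probabilities, mid p-values and
exact critical differences.  Everything is carried out in unbounded integer
/ exact rational arithmetic; floating point appears only in the display
fields of :class:`ExactResult`.

Two independent evaluation routes are provided on purpose:

* a closed-form summation derived from the probability generating function
  of the per-block difference (a triple sum for point counts, reduced to a
  single inner sum for tail counts), and
* a literal n-fold integer convolution of the per-block multiplicity
  vector (:func:`build_distribution`).

They agree exactly on every mass point; the convolution serves as the
oracle in the test-suite and for moderate designs, the summation scales to
large (k, n) where the convolution would be too wide.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial
from numbers import Rational

from .errors import DomainError

__all__ = [
    "DiffDistribution",
    "ExactResult",
    "count_compositions",
    "build_distribution",
    "tail_count",
    "pvalue_ge_signed",
    "pvalue_ge",
    "point_probability",
    "mid_pvalue",
    "exact_result",
    "critical_difference_exact",
]


def _binom(a: int, b: int) -> int:
    """Generalized binomial coefficient with integer arguments.

    Zero for b < 0; the ordinary coefficient for 0 <= b <= a; zero for
    0 <= a < b; and the falling-factorial extension
    a(a-1)...(a-b+1)/b! when the upper index is negative.  The closed-form
    count and tail summations rely on this out-of-range behaviour.
    """
    if b < 0:
        return 0
    if a >= 0:
        return comb(a, b) if a >= b else 0
    num = 1
    for i in range(b):
        num *= a - i
    return num // factorial(b)


def _check_design(k: int, n: int) -> None:
    if k < 2:
        raise DomainError(f"number of groups k must be >= 2, got {k}")
    if n < 1:
        raise DomainError(f"number of blocks n must be >= 1, got {n}")


def _check_support(d: int, k: int, n: int) -> None:
    _check_design(k, n)
    if abs(d) > n * (k - 1):
        raise DomainError(
            f"difference d={d} outside the support [-{n * (k - 1)}, {n * (k - 1)}] "
            f"for k={k}, n={n}"
        )


def total_configurations(k: int, n: int) -> int:
    """Number of equally likely ordered rank-pair configurations, {k(k-1)}^n."""
    return (k * (k - 1)) ** n


@functools.lru_cache(maxsize=100_000)
def count_compositions(d: int, k: int, n: int) -> int:
    """Number of rank configurations giving rank-sum difference exactly d.

    Closed-form triple summation obtained from the probability generating
    function of the per-block rank difference.  Exact integer arithmetic
    throughout; symmetric in the sign of d.
    """
    _check_support(d, k, n)
    total = 0
    for h in range(n + 1):
        inner = 0
        for i in range(h + 1):
            ch_i = comb(h, i)
            for j in range(h + 1):
                a = k * (j - i) - d + h - 1
                b = k * (j - i) - d - h
                c = _binom(a, b)
                if c:
                    term = ch_i * comb(h, j) * c
                    inner += -term if (j - i) % 2 else term
        total += comb(n, h) * k ** (n - h) * inner
    return -total if n % 2 else total


@functools.lru_cache(maxsize=100_000)
def tail_count(d: int, k: int, n: int) -> int:
    """Number of configurations with signed difference >= d (exact integer).

    For d >= 1 this is the single-inner-sum reduction of the generating
    function tail; for d <= 0 it is obtained from the symmetry of the
    distribution, W(D >= d) = {k(k-1)}^n - W(D >= -d + 1), because the
    summation identity only covers nonnegative d.
    """
    _check_support(d, k, n)
    if d <= 0:
        if -d + 1 > n * (k - 1):  # d = -n(k-1): the tail is the whole support
            return total_configurations(k, n)
        return total_configurations(k, n) - tail_count(-d + 1, k, n)
    total = 0
    for h in range(n + 1):
        inner = 0
        for s in range(h + 1):
            c = _binom(k * s - d + h, k * s - d - h)
            if c:
                term = comb(2 * h, h + s) * c
                inner += -term if s % 2 else term
        total += comb(n, h) * k ** (n - h) * inner
    return -total if n % 2 else total


@dataclass(frozen=True)
class DiffDistribution:
    """Exact composition counts of D = R_i - R_j over the signed support.

    ``counts[i]`` is the number of configurations with difference
    d = i - n(k-1); the vector has length 2n(k-1) + 1, sums to
    {k(k-1)}^n, is symmetric, and equals 1 at both endpoints.
    """

    k: int
    n: int
    counts: tuple[int, ...]

    @property
    def max_d(self) -> int:
        return self.n * (self.k - 1)

    @property
    def total(self) -> int:
        return total_configurations(self.k, self.n)

    def count(self, d: int) -> int:
        _check_support(d, self.k, self.n)
        return self.counts[d + self.max_d]

    def prob(self, d: int) -> Fraction:
        """Point probability P(D = d) on the signed support."""
        return Fraction(self.count(d), self.total)

    def tail(self, d: int) -> Fraction:
        """Signed upper-tail probability P(D >= d)."""
        _check_support(d, self.k, self.n)
        return Fraction(sum(self.counts[d + self.max_d:]), self.total)

    def moment(self, order: int) -> Fraction:
        """Exact raw moment E[D^order] of the null distribution."""
        m = self.max_d
        acc = Fraction(0)
        for i, w in enumerate(self.counts):
            if w:
                acc += w * Fraction((i - m) ** order)
        return acc / self.total


def build_distribution(k: int, n: int) -> DiffDistribution:
    """Exact distribution by n-fold integer convolution of one block.

    The per-block multiplicity vector is k - |t| for 1 <= |t| <= k - 1 and
    zero at t = 0.  This is the independent oracle route: it never touches
    the closed-form summations.
    """
    _check_design(k, n)
    block = [k - abs(t) if t else 0 for t in range(-(k - 1), k)]
    out = [1]
    for _ in range(n):
        new = [0] * (len(out) + len(block) - 1)
        for i, a in enumerate(out):
            if a:
                for j, b in enumerate(block):
                    if b:
                        new[i + j] += a * b
        out = new
    return DiffDistribution(k=k, n=n, counts=tuple(out))


def pvalue_ge_signed(d: int, k: int, n: int) -> Fraction:
    """One-sided upper-tail probability P(D >= d) on the signed support."""
    _check_support(d, k, n)
    return Fraction(tail_count(d, k, n), total_configurations(k, n))


def _as_difference(d) -> Fraction:
    """Validate an observed absolute difference: integer or integer + 1/2."""
    dd = Fraction(d)
    if dd.denominator not in (1, 2):
        raise DomainError(
            f"difference d={d} must be an integer or an integer plus 0.5"
        )
    if dd < 0:
        raise DomainError(f"absolute difference d={d} must be nonnegative")
    return dd


def pvalue_ge(d: int, k: int, n: int) -> Fraction:
    """Exact two-sided p-value P(D >= |d|) of an observed difference d >= 0.

    The signed distribution is symmetric, so for d >= 1 the p-value folds to
    twice the signed upper tail.  For d = 0 the folded sum
    P(D = 0) + P(D >= 1) equals 1 exactly, and 1 is returned rather than the
    doubled (>1) tail.
    """
    dd = _as_difference(d)
    if dd.denominator != 1:
        raise DomainError(
            f"d={d} is half-integer (tied ranks); use mid_pvalue for tied data"
        )
    d = int(dd)
    _check_support(d, k, n)
    if d == 0:
        return Fraction(1)
    return 2 * pvalue_ge_signed(d, k, n)


def point_probability(d: int, k: int, n: int) -> Fraction:
    """Probability P(|D| = d) of the folded (absolute-difference) statistic."""
    dd = _as_difference(d)
    if dd.denominator != 1:
        return Fraction(0)
    d = int(dd)
    _check_support(d, k, n)
    p = Fraction(count_compositions(d, k, n), total_configurations(k, n))
    return p if d == 0 else 2 * p


def mid_pvalue(d, k: int, n: int) -> Fraction:
    """Mid p-value: half the point probability plus the strict tail.

    For integer d this is P(|D| > d) + P(|D| = d)/2.  For a half-integer
    difference arising from tied (midrank) data it is the average of the
    exact p-values at the two adjacent integers, which coincides with the
    mid p-value by construction.  Half-integer results are not exact
    frequency probabilities; they inherit the usual mid-p caveat.
    """
    dd = _as_difference(d)
    if dd.denominator == 2:
        lo = int(dd - Fraction(1, 2))
        _check_support(lo + 1, k, n)
        return (pvalue_ge(lo, k, n) + pvalue_ge(lo + 1, k, n)) / 2
    d = int(dd)
    _check_support(d, k, n)
    return pvalue_ge(d, k, n) - point_probability(d, k, n) / 2


@dataclass(frozen=True)
class ExactResult:
    """Exact p-value query result for one (d, k, n).

    Rational fields are exact; ``p_real`` / ``mid_real`` are the rounded
    display values (4 decimals by default, as the reference tables print).
    """

    d: Fraction
    k: int
    n: int
    p_exact: Fraction
    p_mid: Fraction
    p_point: Fraction

    digits: int = 4

    @property
    def p_real(self) -> float:
        return round(float(self.p_exact), self.digits)

    @property
    def mid_real(self) -> float:
        return round(float(self.p_mid), self.digits)

    @property
    def tied(self) -> bool:
        return self.d.denominator == 2


def exact_result(d, k: int, n: int, digits: int = 4) -> ExactResult:
    """Bundle exact, mid and point probabilities for an observed difference."""
    dd = _as_difference(d)
    if dd.denominator == 2:
        p_exact = mid_pvalue(dd, k, n)  # mid-p path; flagged via .tied
    else:
        p_exact = pvalue_ge(int(dd), k, n)
    return ExactResult(
        d=dd,
        k=k,
        n=n,
        p_exact=p_exact,
        p_mid=mid_pvalue(dd, k, n),
        p_point=point_probability(dd, k, n),
        digits=digits,
    )


def critical_difference_exact(k: int, n: int, alpha=0.05, m: int = 1) -> int:
    """Smallest d with Bonferroni-adjusted exact p-value strictly below alpha.

    ``m`` is the number of simultaneous comparisons (1 unadjusted, k - 1 for
    one-control, k(k-1)/2 for all-pairs).  The adjusted p-value
    min(1, m * P(D >= d)) is strictly decreasing wherever mass remains, so a
    bisection over [1, n(k-1)] locates the threshold.  Comparison against
    alpha is done in exact rational arithmetic (a float alpha is interpreted
    through its decimal representation).

    Raises
    ------
    DomainError
        If even the extreme difference d = n(k-1) is not significant, i.e.
        no attainable critical difference exists for this design.
    """
    _check_design(k, n)
    if m < 1:
        raise DomainError(f"number of comparisons m must be >= 1, got {m}")
    alpha = alpha if isinstance(alpha, Rational) else Fraction(str(alpha))
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    dmax = n * (k - 1)

    def significant(d: int) -> bool:
        return min(Fraction(1), m * pvalue_ge(d, k, n)) < alpha

    if not significant(dmax):
        raise DomainError(
            f"no attainable critical difference: even d={dmax} has adjusted "
            f"p >= {alpha} for k={k}, n={n}, m={m}"
        )
    lo, hi = 0, dmax  # invariant: lo not significant, hi significant
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if significant(mid):
            hi = mid
        else:
            lo = mid
    return hi
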