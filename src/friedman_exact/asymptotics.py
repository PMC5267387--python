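"""Large-sample approximations for Friedman rank-sum difference tests.

Under the null the difference D = R_i - R_j has mean 0, variance
nk(k+1)/6 and (Whitfield's) kurtosis 3 - 3/(5n) - 12/(5nk) - 6/(5nk(k+1)),
which is below 3 for every finite n: the discrete distribution has thinner
tails than the normal, and the classical approximations exploit the known
null variance.

Implemented here are the recommended approximate tests and their critical
differences (CDs):

* normal (with optional continuity correction), Bonferroni-adjusted for
  m simultaneous comparisons;
* the maximum of k-1 equicorrelated (rho = 1/2) unit normals, the
  Dunnett-type many-one comparison point, computed by deterministic
  quadrature;
* the Studentized range with infinite degrees of freedom (Nemenyi test);
* the chi-squared omnibus-derived bound.

Approximate CDs are rounded up to the smallest integer not less than the
calculated value (a value landing exactly on an integer stays there).
Although the many-one CD is conventionally written with the one-sided
quantile z_{alpha/c1}, the tabulated reference values are reproducible only
with the two-sided quantile z_{alpha/(2 c1)}; two-sided quantiles are used
throughout, for the normal and for the equicoordinate multivariate-normal
maximum alike.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import integrate, optimize
from scipy import stats

from .errors import DomainError
from .exactdist import critical_difference_exact

__all__ = [
    "NullMoments",
    "CDTable",
    "null_moments",
    "correlated_pair_fraction",
    "sd_difference",
    "normal_pvalue",
    "range_pvalue",
    "relative_error",
    "mvn_max_quantile",
    "cd_normal",
    "cd_mvn_max",
    "cd_range",
    "cd_chisq",
    "cd_table",
]


def _check_design(k: int, n: int) -> None:
    if k < 2:
        raise DomainError(f"number of groups k must be >= 2, got {k}")
    if n < 1:
        raise DomainError(f"number of blocks n must be >= 1, got {n}")


def _check_alpha(alpha: float) -> None:
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")


@dataclass(frozen=True)
class NullMoments:
    """Exact rational null moments of the rank-sum difference."""

    k: int
    n: int
    mean: Fraction
    variance: Fraction
    kurtosis: Fraction


def null_moments(k: int, n: int) -> NullMoments:
    """Mean 0, variance nk(k+1)/6 and Whitfield's kurtosis, as exact rationals."""
    _check_design(k, n)
    var = Fraction(n * k * (k + 1), 6)
    kurt = (
        Fraction(3)
        - Fraction(3, 5 * n)
        - Fraction(12, 5 * n * k)
        - Fraction(6, 5 * n * k * (k + 1))
    )
    return NullMoments(k=k, n=n, mean=Fraction(0), variance=var, kurtosis=kurt)


def correlated_pair_fraction(k: int) -> Fraction:
    """Fraction of pairs of distinct rank-sum differences that are correlated.

    Two differences R_i - R_j and R_l - R_m are correlated (rho = 1/2) iff
    they share exactly one group; the proportion of such pairs among all
    unordered pairs of distinct differences is 4/(k+1).
    """
    if k < 3:
        raise DomainError(f"correlated pairs require k >= 3, got {k}")
    return Fraction(4, k + 1)


def sd_difference(k: int, n: int) -> float:
    """Null standard deviation of D, sqrt(nk(k+1)/6)."""
    _check_design(k, n)
    return math.sqrt(n * k * (k + 1) / 6)


def normal_pvalue(d: float, k: int, n: int, continuity: bool = False) -> float:
    """Two-sided normal-approximate p-value 2(1 - Phi((d - c)/sd)).

    ``c`` is 0.5 with continuity correction, else 0.  Clipped to (0, 1].
    """
    _check_design(k, n)
    if d < 0 or d > n * (k - 1):
        raise DomainError(
            f"difference d={d} outside [0, {n * (k - 1)}] for k={k}, n={n}"
        )
    c = 0.5 if continuity else 0.0
    z = max(d - c, 0.0) / sd_difference(k, n)
    return min(1.0, 2.0 * stats.norm.sf(z))


def range_pvalue(d: float, k: int, n: int) -> float:
    """Studentized-range approximate p-value of an absolute difference.

    The standardized statistic sqrt(2) d / sd(D) is referred to the range
    distribution of k independent unit normals (infinite degrees of
    freedom); the range of all k groups is considered simultaneously, so no
    further multiplicity adjustment is applied.
    """
    _check_design(k, n)
    if d < 0 or d > n * (k - 1):
        raise DomainError(
            f"difference d={d} outside [0, {n * (k - 1)}] for k={k}, n={n}"
        )
    q = math.sqrt(2.0) * d / sd_difference(k, n)
    return float(stats.studentized_range.sf(q, k, np.inf))


def relative_error(d: int, k: int, n: int, continuity: bool = False) -> float:
    """Percentage relative error of the normal p-value against the exact one.

    100 * (P_normal(d - c) - P_exact(d)) / P_exact(d); positive values mean
    the normal approximation overestimates the true tail probability.
    """
    from .exactdist import pvalue_ge

    p_exact = pvalue_ge(d, k, n)
    if p_exact == 0:
        raise DomainError("exact p-value is zero; relative error undefined")
    p_norm = normal_pvalue(d, k, n, continuity=continuity)
    return 100.0 * (p_norm - float(p_exact)) / float(p_exact)


def _mvn_max_cdf(m: float, num: int) -> float:
    """P(max_i |X_i| <= m) for num equicorrelated (rho=1/2) unit normals.

    With rho = 1/2 the variables factor as X_i = (Z + Y_i)/sqrt(2) over a
    shared latent Z, so the equicoordinate probability is a one-dimensional
    integral of a product of conditional normal probabilities.
    """
    s = math.sqrt(2.0)

    def integrand(z: float) -> float:
        return stats.norm.pdf(z) * (
            stats.norm.cdf(m * s - z) - stats.norm.cdf(-m * s - z)
        ) ** num

    val, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-11, epsrel=1e-11)
    return val


@functools.lru_cache(maxsize=64)
def mvn_max_quantile(alpha: float, num: int) -> float:
    """Two-sided equicoordinate quantile of num equicorrelated unit normals.

    The point m with P(max_i |X_i| <= m) = 1 - alpha, common correlation
    1/2 (the Dunnett many-one critical point at infinite degrees of
    freedom).  Deterministic quadrature plus bracketed root-finding;
    accurate to about 1e-5.  For num = 1 this is the ordinary two-sided
    normal critical point.
    """
    _check_alpha(alpha)
    if num < 1:
        raise DomainError(f"need at least one comparison, got {num}")
    if num == 1:
        return float(stats.norm.isf(alpha / 2))
    target = 1.0 - alpha
    lo = float(stats.norm.isf(alpha / 2))
    hi = float(stats.norm.isf(alpha / (2 * num))) + 1.0
    try:
        return float(
            optimize.brentq(
                lambda m: _mvn_max_cdf(m, num) - target, lo, hi, xtol=1e-6
            )
        )
    except ValueError as err:  # pragma: no cover - defensive
        raise DomainError(
            f"equicoordinate quantile search failed on bracket [{lo}, {hi}]: {err}"
        ) from err


def _ceil_cd(value: float) -> int:
    return math.ceil(value)


def cd_normal(k: int, n: int, alpha: float = 0.05, m: int = 1) -> int:
    """Normal-approximate critical difference, Bonferroni-adjusted for m tests."""
    _check_design(k, n)
    _check_alpha(alpha)
    if m < 1:
        raise DomainError(f"number of comparisons m must be >= 1, got {m}")
    z = float(stats.norm.isf(alpha / (2 * m)))
    return _ceil_cd(z * sd_difference(k, n))


def cd_mvn_max(k: int, n: int, alpha: float = 0.05) -> int:
    """Many-one (1xN) critical difference from the equicorrelated-normal maximum."""
    _check_design(k, n)
    _check_alpha(alpha)
    return _ceil_cd(mvn_max_quantile(alpha, k - 1) * sd_difference(k, n))


def cd_range(k: int, n: int, alpha: float = 0.05) -> int:
    """All-pairs (NxN) critical difference from the Studentized range, df = inf."""
    _check_design(k, n)
    _check_alpha(alpha)
    q = float(stats.studentized_range.isf(alpha, k, np.inf))
    return _ceil_cd(q / math.sqrt(2.0) * sd_difference(k, n))


def cd_chisq(k: int, n: int, alpha: float = 0.05) -> int:
    """Critical difference from the chi-squared omnibus bound (df = k - 1)."""
    _check_design(k, n)
    _check_alpha(alpha)
    return _ceil_cd(math.sqrt(stats.chi2.isf(alpha, k - 1)) * sd_difference(k, n))


@dataclass(frozen=True)
class CDTable:
    """Exact and approximate critical differences for one (k, n, alpha) design.

    ``None`` in any slot marks a critical difference exceeding the maximum
    attainable difference max(d) = n(k-1): no rank-sum difference of that
    design can be significant by that test.
    """

    k: int
    n: int
    alpha: float
    max_d: int
    exact: int | None
    exact_one_control: int | None
    exact_all_pairs: int | None
    normal: int
    normal_one_control: int
    normal_all_pairs: int
    mvn_max: int
    range_: int
    chisq: int

    def _mark(self, value: int | None) -> str:
        if value is None:
            return f">max(d)={self.max_d}"
        return str(value) if value <= self.max_d else f"{value} (>max(d)={self.max_d})"

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "alpha": self.alpha,
            "max_d": self.max_d,
            "CD_exact": self._mark(self.exact),
            "CD_exact_1xN": self._mark(self.exact_one_control),
            "CD_exact_NxN": self._mark(self.exact_all_pairs),
            "CD_N": self._mark(self.normal),
            "CD_N_1xN": self._mark(self.normal_one_control),
            "CD_N_NxN": self._mark(self.normal_all_pairs),
            "CD_M_1xN": self._mark(self.mvn_max),
            "CD_Q_NxN": self._mark(self.range_),
            "CD_chisq": self._mark(self.chisq),
        }


def cd_table(k: int, n: int, alpha: float = 0.05) -> CDTable:
    """All critical differences (unadjusted, 1xN, NxN) for one design."""
    _check_design(k, n)
    _check_alpha(alpha)
    c1 = k - 1
    c2 = k * (k - 1) // 2

    def exact_or_none(m: int) -> int | None:
        try:
            return critical_difference_exact(k, n, alpha, m)
        except DomainError:
            return None

    return CDTable(
        k=k,
        n=n,
        alpha=alpha,
        max_d=n * (k - 1),
        exact=exact_or_none(1),
        exact_one_control=exact_or_none(c1),
        exact_all_pairs=exact_or_none(c2),
        normal=cd_normal(k, n, alpha, 1),
        normal_one_control=cd_normal(k, n, alpha, c1),
        normal_all_pairs=cd_normal(k, n, alpha, c2),
        mvn_max=cd_mvn_max(k, n, alpha),
        range_=cd_range(k, n, alpha),
        chisq=cd_chisq(k, n, alpha),
    )
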