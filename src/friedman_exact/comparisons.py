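"""Rank transformation, the Friedman omnibus statistic, and post-hoc drivers.

The post-hoc driver :func:`pairwise_compare` combines the exact engine
(:mod:`~friedman_exact.exactdist`) with the normal and Studentized-range
approximations (:mod:`~friedman_exact.asymptotics`), applying a Bonferroni
familywise correction with multiplier k - 1 (one-control, "1xN") or
k(k-1)/2 (all-pairs, "NxN").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from . import asymptotics, exactdist
from .errors import DomainError, ValidationError

__all__ = [
    "RankMatrix",
    "RankSums",
    "FriedmanResult",
    "ComparisonTable",
    "rank_transform",
    "rank_sums",
    "friedman_statistic",
    "pairwise_compare",
]


@dataclass(frozen=True)
class RankMatrix:
    """Within-block ranks: n blocks (rows) x k groups (columns).

    Each row is a permutation of 1..k, or midranks when ties are present;
    either way every row sums to k(k+1)/2.
    """

    ranks: pd.DataFrame
    has_ties: bool = False

    @property
    def n(self) -> int:
        return self.ranks.shape[0]

    @property
    def k(self) -> int:
        return self.ranks.shape[1]

    @property
    def groups(self) -> list:
        return list(self.ranks.columns)

    def validate(self) -> None:
        k = self.k
        expected = k * (k + 1) / 2
        sums = self.ranks.sum(axis=1)
        bad = sums[~np.isclose(sums, expected)]
        if len(bad):
            raise ValidationError(
                f"block(s) {list(bad.index)} do not sum to k(k+1)/2 = {expected}; "
                "rows must be (mid)rank permutations of 1..k"
            )


@dataclass(frozen=True)
class RankSums:
    """Per-group rank sums R_j over the n blocks."""

    sums: pd.Series
    k: int
    n: int

    @classmethod
    def from_matrix(cls, ranks: RankMatrix) -> "RankSums":
        return cls(sums=ranks.ranks.sum(axis=0), k=ranks.k, n=ranks.n)


def rank_transform(raw, direction: str = "ascending") -> RankMatrix:
    """Rank raw scores within each block; midranks for ties.

    ``direction="ascending"`` gives rank 1 to the smallest score within a
    block (the classical convention); ``"descending"`` gives rank 1 to the
    largest (common when ranking classifiers by a score where larger is
    better).  Input already on the rank scale passes through unchanged
    under the ascending direction.
    """
    if direction not in ("ascending", "descending"):
        raise ValidationError(f"unknown direction {direction!r}")
    df = pd.DataFrame(raw)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"missing cell at block {df.index[i]!r}, group {df.columns[j]!r}: "
            "complete layouts only; route incomplete designs through the "
            "incomplete-design workflow"
        )
    if direction == "descending":
        values = -values
    ranked = np.apply_along_axis(stats.rankdata, 1, values)
    has_ties = any(len(np.unique(row)) < len(row) for row in values)
    return RankMatrix(
        ranks=pd.DataFrame(ranked, index=df.index, columns=df.columns),
        has_ties=has_ties,
    )


def rank_sums(ranks: RankMatrix) -> RankSums:
    """Per-group rank sums; total is nk(k+1)/2."""
    return RankSums.from_matrix(ranks)


@dataclass(frozen=True)
class FriedmanResult:
    """Friedman omnibus statistic with its chi-squared approximation."""

    statistic: Fraction
    df: int
    p_approx: float
    tied: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        note = " (ties present; statistic not tie-corrected)" if self.tied else ""
        return (
            f"Friedman X_r^2 = {float(self.statistic):g}, df = {self.df}, "
            f"chi-squared p = {self.p_approx:.4g}{note}"
        )


def friedman_statistic(ranks: RankMatrix) -> FriedmanResult:
    """Friedman's X_r^2 = 12/(nk(k+1)) * sum_j (R_j - n(k+1)/2)^2.

    The statistic is returned as an exact rational (ranks are integers or
    half-integers); the p-value is the chi-squared upper tail with k - 1
    degrees of freedom.  With tied data the classical tie correction is not
    applied; the ``tied`` flag marks such results.
    """
    ranks.validate()
    k, n = ranks.k, ranks.n
    sums = [Fraction(int(s), 2) for s in (2 * ranks.ranks.sum(axis=0)).round().astype(int)]
    expect = Fraction(n * (k + 1), 2)
    ss = sum((s - expect) ** 2 for s in sums)
    statistic = Fraction(12, n * k * (k + 1)) * ss
    p = float(stats.chi2.sf(float(statistic), k - 1))
    return FriedmanResult(statistic=statistic, df=k - 1, p_approx=p, tied=ranks.has_ties)


@dataclass(frozen=True)
class ComparisonTable:
    """Per-pair post-hoc results.

    ``table`` columns: group_a, group_b, d (absolute rank-sum difference),
    p_exact, p_mid, p_normal, p_range, p_exact_bonf, p_normal_bonf,
    significant.  The Bonferroni multiplier is k - 1 (one-control mode) or
    k(k-1)/2 (all-pairs); adjusted p-values are capped at 1 and a pair is
    flagged significant when its adjusted exact p-value is strictly below
    alpha.  Half-integer differences (tied data) take the mid-p route for
    their "exact" column and are flagged in ``tied_pairs``.
    """

    table: pd.DataFrame
    mode: str
    alpha: float
    k: int
    n: int
    m_comparisons: int
    control: str | None = None
    tied_pairs: tuple = field(default_factory=tuple)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def to_frame(self, digits: int = 4) -> pd.DataFrame:
        out = self.table.copy()
        for col in out.columns:
            if col.startswith("p_"):
                out[col] = out[col].map(lambda p: round(float(p), digits))
        return out


def _coerce_sums(data, n):
    """Accept a RankMatrix, RankSums, or a mapping/Series of rank sums."""
    if isinstance(data, RankMatrix):
        rs = RankSums.from_matrix(data)
        return rs, data.has_ties
    if isinstance(data, RankSums):
        return data, any(Fraction(2 * s) % 2 for s in (2 * data.sums).round().astype(int))
    sums = pd.Series(dict(data) if isinstance(data, dict) else data, dtype=float)
    if n is None:
        raise ValidationError("n (number of blocks) is required when passing rank sums")
    k = len(sums)
    total = sums.sum()
    if not np.isclose(total, n * k * (k + 1) / 2):
        raise ValidationError(
            f"rank sums total {total} != nk(k+1)/2 = {n * k * (k + 1) / 2} "
            f"for k={k}, n={n}"
        )
    tied = bool(np.any((2 * sums.to_numpy()).round() % 2))
    return RankSums(sums=sums, k=k, n=n), tied


def pairwise_compare(
    data,
    mode: str = "all-pairs",
    control: str | None = None,
    alpha: float = 0.05,
    n: int | None = None,
) -> ComparisonTable:
    """Simultaneous pairwise rank-sum difference tests.

    Parameters
    ----------
    data : RankMatrix, RankSums, Series or mapping
        Either the full rank layout or just the per-group rank sums (then
        ``n`` must be given).
    mode : {"all-pairs", "one-control"}
        All k(k-1)/2 pairs, or the k - 1 comparisons against ``control``.
    control : group label, required in one-control mode.
    alpha : familywise significance level (strict inequality).
    """
    rs, tied = _coerce_sums(data, n)
    sums, k, nblocks = rs.sums, rs.k, rs.n
    if sums.index.duplicated().any():
        raise ValidationError(
            f"duplicate group labels: {sorted(sums.index[sums.index.duplicated()])}"
        )
    if mode not in ("all-pairs", "one-control"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "one-control":
        if control is None:
            raise ValidationError("one-control mode requires a control group")
        if control not in sums.index:
            raise ValidationError(f"unknown control group {control!r}")
        pairs = [(control, g) for g in sums.index if g != control]
        m = k - 1
    else:
        if control is not None:
            raise ValidationError("control is only meaningful in one-control mode")
        labels = list(sums.index)
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
        m = k * (k - 1) // 2

    rows = []
    tied_pairs = []
    one = Fraction(1)
    for a, b in pairs:
        d = Fraction(2 * abs(sums[a] - sums[b])).limit_denominator(1) / 2
        res = exactdist.exact_result(d, k, nblocks)
        if res.tied:
            tied_pairs.append((a, b))
        p_exact = res.p_exact
        p_mid = res.p_mid
        p_norm = asymptotics.normal_pvalue(float(d), k, nblocks)
        p_rng = asymptotics.range_pvalue(float(d), k, nblocks)
        pe_adj = min(one, m * p_exact)
        pn_adj = min(1.0, m * p_norm)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "d": float(d),
                "p_exact": p_exact,
                "p_mid": p_mid,
                "p_normal": p_norm,
                "p_range": p_rng,
                "p_exact_bonf": pe_adj,
                "p_normal_bonf": pn_adj,
                "significant": pe_adj < Fraction(str(alpha)),
            }
        )
    table = pd.DataFrame(rows)
    return ComparisonTable(
        table=table,
        mode=mode,
        alpha=alpha,
        k=k,
        n=nblocks,
        m_comparisons=m,
        control=control,
        tied_pairs=tuple(tied_pairs),
    )
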