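"""Exact p-values for incomplete designs via convolution of design parts.

Blocks are independent, so a design whose blocks split into parts with
different numbers of present groups — say n_1 blocks ranking k_1 groups and
n_2 blocks ranking only k_2 of them — still admits an exact test for any
pair of groups present in *every* part: the total difference D = sum_t D_t
is the sum of independent per-part differences, and its exact distribution
is the convolution of the per-part signed distributions.

P(D >= d) = sum_i P(D_1 = i; k_1, n_1) P(D_2 >= d - i; k_2, n_2), iterated
for more parts.  Everything stays in exact integer counts; folding to the
two-sided p-value of |d| happens once, at the end.

Pairs with one member absent from some part are rejected: the difference is
then not a sum of within-part differences and the convolution does not
apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .errors import DomainError
from .exactdist import DiffDistribution, build_distribution

__all__ = ["DesignPart", "convolve_parts", "pvalue_parts_signed", "pvalue_parts"]


@dataclass(frozen=True)
class DesignPart:
    """One complete sub-layout: n_t blocks each ranking k_t groups."""

    k: int
    n: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise DomainError(f"part needs k >= 2 groups, got {self.k}")
        if self.n < 1:
            raise DomainError(f"part needs n >= 1 blocks, got {self.n}")

    @property
    def max_d(self) -> int:
        return self.n * (self.k - 1)


def _as_parts(parts: Iterable) -> list[DesignPart]:
    out = [p if isinstance(p, DesignPart) else DesignPart(*p) for p in parts]
    if not out:
        raise DomainError("at least one design part is required")
    return out


def convolve_parts(parts: Sequence) -> tuple[tuple[int, ...], int, int]:
    """Convolved signed counts over the combined support.

    Returns ``(counts, max_d, total)`` where ``counts[i]`` is the exact
    integer count for total difference d = i - max_d and ``total`` is the
    product of the per-part configuration counts.  Parts are processed in
    increasing support width to keep intermediate vectors small; the result
    is order-invariant.
    """
    parts = sorted(_as_parts(parts), key=lambda p: p.max_d)
    counts: list[int] = [1]
    total = 1
    for part in parts:
        dist: DiffDistribution = build_distribution(part.k, part.n)
        total *= dist.total
        new = [0] * (len(counts) + len(dist.counts) - 1)
        for i, a in enumerate(counts):
            if a:
                for j, b in enumerate(dist.counts):
                    if b:
                        new[i + j] += a * b
        counts = new
    max_d = sum(p.max_d for p in parts)
    return tuple(counts), max_d, total


def pvalue_parts_signed(d: int, parts: Sequence) -> Fraction:
    """Exact one-sided tail P(D >= d) of the convolved signed distribution."""
    counts, max_d, total = convolve_parts(parts)
    if abs(d) > max_d:
        raise DomainError(
            f"difference d={d} outside the combined support [-{max_d}, {max_d}]"
        )
    return Fraction(sum(counts[d + max_d:]), total)


def pvalue_parts(d: int, parts: Sequence) -> Fraction:
    """Exact two-sided p-value P(D >= |d|) for an incomplete design.

    For a single part this reduces exactly to the complete-design p-value;
    for several parts with a common k it equals the complete-design value
    at the pooled block count.  ``d = 0`` returns 1 exactly, as in the
    complete case.
    """
    d = abs(int(d))
    if d == 0:
        # folded mass P(D=0) + P(D>=1) covers the whole support
        _as_parts(parts)
        return Fraction(1)
    return 2 * pvalue_parts_signed(d, parts)
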