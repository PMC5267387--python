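"""Exact-distribution engine: oracle agreement, invariants, frozen values."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from friedman_exact import exactdist as ed
from friedman_exact.errors import DomainError

SMALL_DESIGNS = [(k, n) for k in range(2, 7) for n in range(1, 7)]


@pytest.fixture(scope="module")
def small_distributions():
    return {(k, n): ed.build_distribution(k, n) for k, n in SMALL_DESIGNS}


class TestDistributionInvariants:
    @pytest.mark.parametrize("k,n", SMALL_DESIGNS)
    def test_support_normalization_symmetry_extremes(self, small_distributions, k, n):
        dist = small_distributions[(k, n)]
        counts = dist.counts
        assert len(counts) == 2 * n * (k - 1) + 1
        assert sum(counts) == (k * (k - 1)) ** n
        assert counts == counts[::-1]
        assert counts[0] == counts[-1] == 1

    def test_two_groups_single_block(self):
        assert ed.build_distribution(2, 1).counts == (1, 0, 1)

    def test_k3_n2_counts(self):
        # per-block multiplicities (2,1,0,1,2) convolved once with themselves
        assert ed.build_distribution(3, 2).counts == (1, 4, 4, 4, 10, 4, 4, 4, 1)


class TestClosedFormAgainstConvolutionOracle:
    @pytest.mark.parametrize("k,n", SMALL_DESIGNS)
    def test_point_counts_match(self, small_distributions, k, n):
        dist = small_distributions[(k, n)]
        m = n * (k - 1)
        for d in range(-m, m + 1):
            assert ed.count_compositions(d, k, n) == dist.counts[d + m]

    @pytest.mark.parametrize("k,n", SMALL_DESIGNS)
    def test_signed_tails_match(self, small_distributions, k, n):
        dist = small_distributions[(k, n)]
        m = n * (k - 1)
        for d in range(-m, m + 1):
            assert ed.pvalue_ge_signed(d, k, n) == dist.tail(d)

    @pytest.mark.parametrize("k,n", SMALL_DESIGNS)
    def test_folded_pvalue_doubles_the_tail(self, small_distributions, k, n):
        dist = small_distributions[(k, n)]
        for d in range(1, n * (k - 1) + 1):
            assert ed.pvalue_ge(d, k, n) == 2 * dist.tail(d)

    def test_triple_sum_equals_single_sum_route(self):
        # the cumulative count by summing point counts (triple sum) agrees
        # with the single-sum tail reduction
        for k, n in [(3, 3), (4, 2), (5, 2), (6, 1)]:
            m = n * (k - 1)
            for d in range(1, m + 1):
                cumulative = sum(
                    ed.count_compositions(t, k, n) for t in range(d, m + 1)
                )
                assert ed.tail_count(d, k, n) == cumulative


class TestFrozenValues:
    def test_composition_examples(self):
        assert ed.count_compositions(0, 3, 2) == 10
        assert ed.count_compositions(1, 3, 2) == 4
        assert ed.count_compositions(2 * (3 - 1), 3, 2) == 1
        assert ed.count_compositions(5 * 4, 5, 5) == 1

    def test_signed_pvalue_examples(self):
        assert ed.pvalue_ge_signed(1, 3, 2) == Fraction(13, 36)
        assert ed.pvalue_ge_signed(0, 3, 2) == Fraction(23, 36)
        assert ed.pvalue_ge_signed(-2 * 2, 3, 2) == 1

    def test_folded_pvalue_boundaries(self):
        for k, n in [(3, 2), (5, 5), (11, 4)]:
            assert ed.pvalue_ge(0, k, n) == 1
            assert ed.pvalue_ge(n * (k - 1), k, n) == Fraction(
                2, (k * (k - 1)) ** n
            )

    def test_qpcr_scale_pvalue(self):
        # P(D >= 11; 5, 5) = .0326 and its mid companion at one step below
        assert round(float(ed.pvalue_ge(11, 5, 5)), 4) == 0.0326
        assert ed.mid_pvalue(1, 3, 2) == Fraction(22, 36)

    def test_critical_difference_examples(self):
        assert ed.critical_difference_exact(5, 5, 0.05, 1) == 11
        assert ed.critical_difference_exact(11, 4, 0.05, 55) == 30
        assert ed.critical_difference_exact(25, 5, 0.05, 300) == 83


class TestMoments:
    @pytest.mark.parametrize("k,n", SMALL_DESIGNS)
    def test_exact_moments(self, small_distributions, k, n):
        dist = small_distributions[(k, n)]
        assert dist.moment(1) == 0
        assert dist.moment(3) == 0
        var = dist.moment(2)
        assert var == Fraction(n * k * (k + 1), 6)
        kurt = dist.moment(4) / var**2
        expected = (
            Fraction(3)
            - Fraction(3, 5 * n)
            - Fraction(12, 5 * n * k)
            - Fraction(6, 5 * n * k * (k + 1))
        )
        assert kurt == expected
        assert kurt < 3


class TestMonotonicityAndMidP:
    @pytest.mark.parametrize("k,n", [(3, 4), (5, 5), (7, 3)])
    def test_pvalue_nonincreasing_and_positive(self, k, n):
        previous = Fraction(2)
        for d in range(0, n * (k - 1) + 1):
            p = ed.pvalue_ge(d, k, n)
            assert 0 < p <= previous
            previous = p

    @pytest.mark.parametrize("k,n", [(3, 4), (5, 5)])
    def test_mid_below_exact_where_mass_exists(self, k, n):
        for d in range(1, n * (k - 1) + 1):
            p = ed.pvalue_ge(d, k, n)
            mid = ed.mid_pvalue(d, k, n)
            if ed.point_probability(d, k, n) > 0:
                assert mid < p
            else:
                assert mid == p

    def test_half_integer_mid_is_average_of_neighbours(self):
        got = ed.mid_pvalue(Fraction(21, 2), 5, 5)
        expected = (ed.pvalue_ge(10, 5, 5) + ed.pvalue_ge(11, 5, 5)) / 2
        assert got == expected

    def test_exact_result_flags_ties(self):
        res = ed.exact_result(10.5, 5, 5)
        assert res.tied
        assert res.p_exact == res.p_mid
        res = ed.exact_result(11, 5, 5)
        assert not res.tied
        assert res.p_mid < res.p_exact


class TestTypeIErrorBound:
    @pytest.mark.parametrize("k", [5, 10])
    @pytest.mark.parametrize("n", [5, 10])
    def test_exact_cd_brackets_alpha(self, k, n):
        cd = ed.critical_difference_exact(k, n, 0.05, 1)
        assert ed.pvalue_ge(cd, k, n) < Fraction(1, 20)
        assert ed.pvalue_ge(cd - 1, k, n) >= Fraction(1, 20)


class TestDomainErrors:
    def test_rejects_bad_design(self):
        with pytest.raises(DomainError, match="k must be >= 2"):
            ed.count_compositions(0, 1, 3)
        with pytest.raises(DomainError, match="n must be >= 1"):
            ed.build_distribution(3, 0)

    def test_rejects_out_of_support(self):
        with pytest.raises(DomainError, match="outside the support"):
            ed.pvalue_ge(9, 3, 2)
        with pytest.raises(DomainError, match="outside the support"):
            ed.pvalue_ge_signed(-9, 3, 2)

    def test_rejects_non_half_integer(self):
        with pytest.raises(DomainError, match="integer plus 0.5"):
            ed.mid_pvalue(1.25, 5, 5)

    def test_rejects_half_integer_in_plain_pvalue(self):
        with pytest.raises(DomainError, match="mid_pvalue"):
            ed.pvalue_ge(1.5, 5, 5)

    def test_unattainable_critical_difference(self):
        # with a huge Bonferroni multiplier even the extreme d fails
        with pytest.raises(DomainError, match="no attainable"):
            ed.critical_difference_exact(3, 2, 0.05, 100)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    k=st.integers(min_value=2, max_value=8),
    n=st.integers(min_value=1, max_value=6),
    data=st.data(),
)
def test_tail_count_consistency_property(k, n, data):
    """Point and tail counts satisfy W(>=d) - W(>=d+1) = W(=d) everywhere."""
    m = n * (k - 1)
    d = data.draw(st.integers(min_value=-m, max_value=m - 1))
    assert ed.tail_count(d, k, n) - ed.tail_count(d + 1, k, n) == ed.count_compositions(
        d, k, n
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    k=st.integers(min_value=2, max_value=8),
    n=st.integers(min_value=1, max_value=6),
    data=st.data(),
)
def test_symmetry_property(k, n, data):
    """The closed-form point count is symmetric in the sign of d."""
    m = n * (k - 1)
    d = data.draw(st.integers(min_value=0, max_value=m))
    assert ed.count_compositions(d, k, n) == ed.count_compositions(-d, k, n)
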