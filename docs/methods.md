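# Methods

## Null model

Data are a complete two-way layout: k groups ranked 1..k within each of n
independent blocks. Under the global null every within-block permutation
is equally likely, independently across blocks. For a fixed pair of
groups, the per-block difference of their two ranks takes each value
t ∈ {±1, …, ±(k−1)} with multiplicity k − |t| out of the k(k−1) equally
likely ordered rank pairs; the pairwise rank-sum difference D = R_i − R_j
is the n-fold sum of independent copies. Its support is the integer
interval [−n(k−1), n(k−1)] (2n(k−1)+1 mass points), the distribution is
symmetric with mean 0, variance nk(k+1)/6, all odd moments 0, and
kurtosis 3 − 3/(5n) − 12/(5nk) − 6/(5nk(k+1)) < 3 — thinner-tailed than
normal for every finite n, which is why large-sample approximations
overestimate far-tail p-values.

## Exact computation

Two independent routes compute the composition counts W(D = d; k, n):

1. **Closed form.** From the probability generating function of the
   per-block difference, the point count is a triple summation and the
   upper-tail count W(D ≥ d) reduces to a double summation (a single inner
   sum over s of (−1)^s C(2h, h+s) C(ks−d+h, ks−d−h) inside a sum over
   h ≤ n). All arithmetic is unbounded-integer; probabilities are exact
   `fractions.Fraction` values with denominator {k(k−1)}^n.
2. **Convolution oracle.** A literal n-fold integer convolution of the
   per-block multiplicity vector. The test suite asserts entry-wise
   equality of both routes for every d at all k ≤ 6, n ≤ 6, plus
   normalization, symmetry, unit counts at the extremes, and exact moment
   identities.

Out-of-range binomial coefficients in the closed form follow the
generalized convention: C(a, b) = 0 for b < 0, the falling-factorial
extension a(a−1)…(a−b+1)/b! for negative upper index a. This is the
unique convention under which the summations agree with the convolution
everywhere (the often-quoted alternative, zero whenever b < 0 *or*
a < b, breaks already at W(0; 3, 2)). The single-sum tail identity holds
for d ≥ 1; tails at d ≤ 0 use the symmetry W(D ≥ d) = {k(k−1)}^n −
W(D ≥ −d+1), which is exact on the whole support.

The two-sided p-value of an observed |d| ≥ 1 folds the symmetric
distribution: P(D ≥ |d|) = 2 · (signed tail). At d = 0 the folded sum
P(D = 0) + P(D ≥ 1) equals exactly 1, and 1 is returned. The mid p-value
is ½P(D = d) + P(D > d); for half-integer d arising from midranks it is
the average of the exact p-values at the two adjacent integers (the same
quantity by construction). Mid p-values, and every result derived from
tied data, are not exact frequency probabilities and are flagged as such.

Exact critical differences are the smallest d with
min(1, m · P(D ≥ d)) < α (strict inequality), found by bisection — the
adjusted p-value is strictly decreasing wherever mass remains, so the
threshold is unique and no tie-breaking arises. α given as a float is
interpreted through its decimal representation (Fraction(str(α))) so that
.05 means 1/20, not its binary neighbour. When even d = n(k−1) is not
significant the search reports "no attainable critical difference" rather
than a number.

Performance: a single tail evaluation at k = n = 100 takes ~30 ms
(Python integers via `math.comb`; no external big-float dependency), so
bisection over the full support and whole reference grids are desk-scale.
Point and tail counts are memoized.

## Approximations

All quantiles are two-sided. The many-one critical difference is often
written with the one-sided quantile z_{α/(k−1)}, but the reference values
it is expected to reproduce require z_{α/(2(k−1))}; this package follows
the numbers, not the notation, and likewise uses the two-sided
(equicoordinate on |X_i|) version of the multivariate-normal maximum —
for k = 5, n = 5 the one-sided point (≈2.16) would give CD 11, the
two-sided (≈2.49) gives the expected 13.

- **Normal:** CD = ⌈z_{α/(2m)} √(nk(k+1)/6)⌉; p-value
  2(1 − Φ((d − c)/σ)) with continuity correction c = 0.5 optional. The
  diagnostic R(d) = 100(P_normal(d−c) − P_exact(d))/P_exact(d) quantifies
  the approximation error; it is negative (normal too small) at moderate
  d and positive (normal too large) in the far tail.
- **Equicorrelated-normal maximum (Dunnett-type, 1×N):** the quantile m
  with P(max_i |X_i| ≤ m) = 1 − α for k − 1 unit normals with common
  correlation ½. Computed deterministically: the ρ = ½ structure factors
  over one shared latent variable, giving a one-dimensional integral
  ∫φ(z)[Φ(m√2 − z) − Φ(−m√2 − z)]^{k−1}dz evaluated by adaptive
  quadrature (absolute tolerance 1e−11) inside a bracketed root search
  (xtol 1e−6), so results are reproducible bit-for-bit. Five cells of the
  widely-circulated reference grid for this column differ from our values
  by 1–2 units — (k, n) = (10,100): 116 not 115; (100,5): 303 not 302;
  (100,10): 428 not 427; (100,50): 956 not 955; (100,100): 1352 not 1350.
  Those tabulations used Monte-Carlo multivariate-normal quantiles; our
  quadrature agrees with R's `pmvnorm` (GenzBretz, abseps 1e−7) to below
  1e−4 in probability at the disputed points, and the frozen expectations
  in the test suite use the deterministic values.
- **Studentized range (Nemenyi, N×N):** CD = ⌈q_{α,k,∞}/√2 ·
  √(nk(k+1)/6)⌉ and p = P(Q_{k,∞} ≥ √2 d/σ) via
  `scipy.stats.studentized_range` (cross-checked against R `ptukey` to
  6 decimals). No further multiplicity adjustment: the range of all k
  groups is simultaneous by construction.
- **Chi-squared:** CD = ⌈√(χ²_{α,k−1}) √(nk(k+1)/6)⌉. Dominates every
  other critical difference and can exceed max(d) = n(k−1); such cells
  are reported with an explicit out-of-support marker.

Approximate CDs are rounded with a pure ceiling — a value landing exactly
on an integer stays there; no epsilon slack is added.

## Reference-grid adjudications

The frozen expectations in `tests/test_acceptance.py` were verified cell
by cell against the independent convolution oracle and R's distribution
functions. Besides the five Monte-Carlo CD cells above, three further
published cells disagree with exact recomputation and are frozen at the
verified values:

- exact all-pairs CD at (k, n) = (10, 100) is 140, not 141
  (45·P(D ≥ 140) = .04891 < .05 while 45·P(D ≥ 139) = .05315, by both
  computation routes);
- the all-pairs normal CD at (5, 25) is 32, not 33
  (2.80703 × √125 = 31.385; no quantile convention yields 33);
- the Studentized-range p at d = 23 in the qPCR triangles is 0.333468
  (scipy and R agree to 6 dp), i.e. 0.333 at 3 dp, not 0.334.

Four cells of the p-value grid are one unit of the 4th decimal high in
the published version relative to the exact rationals (mid(10;5,5) =
.04394968, P(D≥46;25,5) = .04934641, P(D≥103;25,25) = .04864792,
P(D≥805;100,100) = .04984779); the exact values are asserted. In that
grid the second column is the mid p-value evaluated at one rank-sum
difference *below* the exact critical difference — the mid p of the
largest non-significant difference, which can exceed α — not the mid p at
the CD itself.

## Incomplete designs

When blocks split into complete parts (k_t, n_t) — e.g. some blocks rank
only a subset of groups because the remaining methods are inapplicable by
design — the total difference for a pair present in every part is the sum
of independent per-part differences, and its exact distribution is the
integer convolution of the per-part signed distributions. Parts are
convolved in increasing support width (a performance choice only; the
result is order-invariant), and folding to the two-sided p-value of |d|
happens once at the end. A single part reduces exactly to the complete
case, and splitting a common-k design into parts changes nothing — both
laws are asserted exhaustively for k, n ≤ 6. Pairs with a member absent
from some part are outside the model and rejected. Bonferroni multipliers
for incomplete designs use the full group count k (k − 1, resp.
k(k−1)/2), matching how the case study reports them.

## Synthetic data

`fixtures.generate_null` draws each block as an independent uniform
permutation of 1..k (NumPy PCG64; algorithm + seed are the contract), with
optional tie injection that replaces adjacent rank pairs by their midrank
at a given rate, preserving row sums. This emulates exactly the null
model of the exact derivation — exchangeable within-block rankings — and
nothing else: no group effects, no block heterogeneity, no correlated
blocks. Passing uniformity tests therefore validate the machinery, not
the robustness of the Friedman framework on real data (where blocks may
be dependent, as in both packaged case studies' source discussions).

`null_pvalue_uniformity` computes all k(k−1)/2 exact p-values on
simulated null matrices. The p-values of one matrix derive from only k
rank sums and are strongly dependent, so single-realization summaries
(one published example reports mean 0.512, variance 0.0824 at k = 50,
n = 5) are seed noise; the summary pools a configurable number of
replicate matrices, and the tests check mean 0.5 ± 0.03 and variance
1/12 ± 0.01 over 20 pooled replicates at fixed seeds. Problem sizes
throughout the suite (k, n ≤ 6 exhaustively; the 25-design grid up to
k = n = 100; 20 replicate matrices at k = 50, n = 5) were chosen as the
smallest sizes that exercise every code path and the published grids in
full.

## Tied data

Midranks make the omnibus statistic conservative; the classical tie
correction is deliberately not applied (out of scope) and tied results
are flagged instead. Pairwise differences involving midranks can be
half-integers; these take the mid-p route described above.

## Known limitations

- The exact engine covers the pairwise difference distribution, not the
  joint distribution of all k rank sums (no exact omnibus test).
- Bonferroni is the only familywise adjustment; step-down/step-up
  procedures (Holm, Hochberg, Hommel) are out of scope.
- The Studentized range is implemented at infinite degrees of freedom
  only, and no rank-score-based t-tests (Conover, Rosenthal–Ferguson)
  are provided.
- Under alternatives, nk(k+1)/6 overestimates Var(d), so all tests here
  (exact included) lose power; nothing in the package estimates power.
- For very large k·n the convolution oracle becomes wide; the closed
  form remains fast (polynomial in n) but memory for exact rationals
  grows with n log k.
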