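# friedman-exact

Exact *p*-values and critical differences for pairwise comparison of
Friedman rank sums.

## The problem

The Friedman test ranks *k* groups (classifiers, treatments, methods)
within each of *n* independent blocks (datasets, subjects, indicators) and
asks whether the rank sums *R*₁, …, *R*ₖ differ. After a significant
omnibus test — or instead of one — the question of practical interest is
*which* pairs differ: one tests the rank-sum differences *d* = *R*ᵢ − *R*ⱼ,
either all *k*(*k* − 1)/2 pairs or *k* − 1 pairs against a control, with a
familywise (Bonferroni) correction.

The standard practice refers *d* to a large-sample approximation — normal,
Dunnett-type equicorrelated-normal maximum, Studentized range (Nemenyi),
or chi-squared. Those approximations are derived for large *n*, while
typical comparisons (e.g. classifiers over benchmark datasets) have small
*n* and often large *k*; in the far tail, exactly where Bonferroni-adjusted
significance is decided, they can be off enough to flip conclusions.

This package computes the **exact** null distribution of *d* instead.
Under the null, every within-block permutation of 1..*k* is equally
likely, so the per-block rank difference of a fixed pair takes value *t*
(1 ≤ |*t*| ≤ *k* − 1) with multiplicity *k* − |*t*| out of *k*(*k* − 1)
ordered rank pairs, and *D* is the *n*-fold sum of independent copies.
The package evaluates the composition counts *W*(*D* = *d*; *k*, *n*) and
tail sums with a closed-form summation derived from the generating
function, in unbounded-integer / exact-rational arithmetic — no floating
point until display. An independent *n*-fold integer convolution of the
per-block multiplicities backs every closed-form value in the test suite.

Provided on top of the exact engine:

- exact two-sided *p*-values *P*(*D* ≥ |*d*|), point probabilities, and
  mid *p*-values (½*P*(*D* = *d*) + *P*(*D* > *d*), also the tie-handling
  route for half-integer *d* from midranks);
- exact critical differences: the smallest *d* with
  min(1, *m*·*P*(*D* ≥ *d*)) < α, found by bisection in exact rationals;
- the recommended approximations and their critical differences
  (normal with optional continuity correction, equicoordinate
  multivariate-normal maximum by deterministic quadrature, Studentized
  range at infinite df, chi-squared), plus the relative-error diagnostic
  *R*(*d*);
- exact *p*-values for **incomplete designs** whose blocks split into
  complete parts (*k*ₜ, *n*ₜ): the distribution of the total difference is
  the convolution of the per-part exact distributions;
- a Friedman omnibus statistic, a pairwise comparison driver producing a
  tidy table, seeded null-data simulation, and a CLI.

## Worked example

The packaged case study compares k = 11 qPCR curve-analysis methods over
n = 4 performance indicators (bias, linearity, precision, resolution),
using their published Friedman rank sums:

```python
from friedman_exact import fixtures, pairwise_compare

res = pairwise_compare(fixtures.qpcr_rank_sums(), mode="all-pairs", n=4)
print(res.to_frame(digits=3).query("significant")[
    ["group_a", "group_b", "d", "p_exact_bonf", "p_normal_bonf", "p_range"]
].to_string(index=False))
```

```
    group_a  group_b    d  p_exact_bonf  p_normal_bonf  p_range
        Cy0 LRE-Emax 31.0         0.018          0.052    0.038
        Cy0  FPK-PCR 33.0         0.005          0.024    0.019
  LinRegPCR  FPK-PCR 30.0         0.033          0.076    0.053
Standard-Cq  FPK-PCR 30.0         0.033          0.076    0.053
```

Four pairs are significant at familywise α = .05 by exact calculation
(Bonferroni-adjusted over the 55 pairs). The normal approximation finds
only one of them (Cy0 vs FPK-PCR, adjusted p = 0.024) and the Studentized
range two — the exact all-pairs critical difference is d = 30, versus 31
for the range test and 32 for the normal. Near the critical value, exact
versus approximate is exactly the difference between "significant" and
"not".

The same from the shell:

```
$ friedman-exact cd --k 11 --n 4 --mode all-pairs --method all
  ...
  "CD_exact_NxN": "30",
  "CD_N_NxN": "32",
  "CD_Q_NxN": "31",
  ...

$ friedman-exact pvalue --k 5 --n 5 --d 11
{
  "k": 5, "n": 5, "d": 11.0, "method": "exact",
  "p": {"value": 0.0326, "exact": "52143/1600000"},
  ...
}
```

Subcommands: `pvalue`, `cd`, `compare FILE` (CSV/TSV two-way layouts,
raw scores or ranks, either orientation), `parts` (incomplete designs,
e.g. `--part 12:9 --part 10:1`), `simulate` (seeded null experiments).

## Incomplete designs

In the second packaged case study (k = 12 data-transformation methods on
n = 10 cell-differentiation datasets) two methods are inapplicable to one
dataset, so that block ranks only 10 methods. Dropping the block gives
d = 37 with P(D ≥ 37; 12, 9) = 0.016; keeping it as a second design part
gives d = 46 with a convolution p-value of 0.003 — the extra partial block
sharpens the conclusion:

```python
from friedman_exact import pvalue_parts
float(pvalue_parts(46, [(12, 9), (10, 1)]))   # 0.00346...
```

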