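"""Seeded synthetic data and the packaged case-study tables.

Null rank matrices are generated with independent uniform permutations per
block (NumPy ``default_rng``, PCG64 — the algorithm and the seed together
form the reproducibility contract).  An optional tie-injection step
replaces adjacent rank pairs by their midrank, preserving the row sum.

Two transcribed case-study tables ship with the package:

* ``qpcr_rank_sums`` — published Friedman rank sums of k = 11 qPCR curve
  analysis methods over n = 4 performance indicators (bias, linearity,
  precision, resolution).
* ``cell_diff_ranks`` — published within-dataset ranks of k = 12 data
  transformation methods over n = 10 cell differentiation datasets, with
  two ranks missing by design in dataset GDS2688 (only 10 methods were
  applicable there).

``qpcr_ranks_synthetic`` is a synthetic 4 x 11 rank layout whose column
sums equal the published qPCR rank sums; the per-indicator ranks are a
reconstruction (only the rank sums are authentic) and serve round-trip and
I/O tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .comparisons import RankMatrix, pairwise_compare
from .errors import ValidationError

__all__ = [
    "SimulationSpec",
    "generate_null",
    "null_pvalue_uniformity",
    "qpcr_rank_sums",
    "qpcr_ranks_synthetic",
    "cell_diff_ranks",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic null experiment.

    ``tie_rate`` is the per-adjacent-rank-pair probability of replacing the
    pair by midranks, in [0, 1).  Identical seeds give identical matrices.
    """

    k: int
    n: int
    seed: int
    tie_rate: float = 0.0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.k < 2 or self.n < 1:
            raise ValidationError(f"invalid design k={self.k}, n={self.n}")
        if not 0 <= self.tie_rate < 1:
            raise ValidationError(f"tie_rate must lie in [0, 1), got {self.tie_rate}")
        if self.replicates < 1:
            raise ValidationError(f"replicates must be >= 1, got {self.replicates}")


def generate_null(spec: SimulationSpec, rng=None) -> RankMatrix:
    """n independent uniform rank permutations of 1..k, optionally tied."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows = np.empty((spec.n, spec.k))
    has_ties = False
    for i in range(spec.n):
        row = rng.permutation(spec.k) + 1.0
        if spec.tie_rate:
            t = 1
            while t < spec.k:
                if rng.random() < spec.tie_rate:
                    a = np.where(row == t)[0][0]
                    b = np.where(row == t + 1)[0][0]
                    row[a] = row[b] = t + 0.5
                    has_ties = True
                    t += 2  # skip the consumed rank
                else:
                    t += 1
        rows[i] = row
    df = pd.DataFrame(
        rows,
        index=[f"block{i + 1}" for i in range(spec.n)],
        columns=[f"g{j + 1}" for j in range(spec.k)],
    )
    return RankMatrix(ranks=df, has_ties=has_ties)


def null_pvalue_uniformity(spec: SimulationSpec) -> dict:
    """Exact all-pairs p-values on one simulated null matrix, summarized.

    Under the global null the exact p-values are approximately uniform on
    [0, 1]; the summary reports their mean (expected 1/2), variance
    (expected 1/12) and the Kolmogorov distance between the empirical
    distribution of 1 - p and the uniform CDF.  The k(k-1)/2 p-values of a
    single matrix are strongly dependent (they derive from only k rank
    sums), so the summary pools ``spec.replicates`` independent matrices
    drawn from one seeded generator stream.
    """
    rng = np.random.default_rng(spec.seed)
    pooled = []
    for _ in range(spec.replicates):
        matrix = generate_null(spec, rng=rng)
        table = pairwise_compare(matrix, mode="all-pairs").table
        pooled.append([float(p) for p in table["p_exact"]])
    pvals = np.array(pooled).ravel()
    sorted_q = np.sort(1.0 - pvals)
    npairs = len(sorted_q)
    hi = np.arange(1, npairs + 1) / npairs - sorted_q
    lo = sorted_q - np.arange(0, npairs) / npairs
    ks = float(np.max(np.maximum(hi, lo)))
    return {
        "k": spec.k,
        "n": spec.n,
        "replicates": spec.replicates,
        "n_pairs": len(pvals),
        "mean": float(pvals.mean()),
        "variance": float(pvals.var(ddof=0)),
        "ks_distance": ks,
    }


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("friedman_exact.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def qpcr_rank_sums() -> pd.Series:
    """Published rank sums of the k=11, n=4 qPCR method comparison."""
    df = _read("qpcr_rank_sums.csv")
    return df.set_index("method")["rank_sum"].astype(float)


def qpcr_ranks_synthetic() -> RankMatrix:
    """Synthetic 4 x 11 rank layout with the published qPCR rank sums."""
    df = _read("qpcr_ranks_synthetic.csv", index_col=0)
    return RankMatrix(ranks=df.astype(float), has_ties=False)


def cell_diff_ranks() -> pd.DataFrame:
    """Published 12 x 10 rank table of the cell-differentiation study.

    Methods as rows, datasets as columns; the two ranks missing by design
    in GDS2688 are NaN.
    """
    return _read("cell_diff_ranks.csv", index_col=0).astype(float)
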