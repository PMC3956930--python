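"""Statistical comparisons of homoplasy between site classes.

Three pieces: Fisher's exact test on the 2x2 table of site class versus
homoplasy (HI = 0, i.e. tree-supporting, against HI = 0.5), a seeded
procedure that distributes sites at random into fixed-size bins and
averages HI within each bin, and a Wilcoxon rank-sum comparison of the two
sets of bin means (exact by enumeration for small samples, normal
approximation with tie and continuity corrections otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of (site class) x (HI value) — rows are classes, columns are
    HI = 0 and HI = 0.5."""

    a: int  # row 1, col 1
    b: int  # row 1, col 2
    c: int  # row 2, col 1
    d: int  # row 2, col 2

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def rows(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def fisher_exact_two_sided(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value.

    The two-sided p is the hypergeometric probability mass of all tables
    with the observed margins whose point probability does not exceed the
    observed table's.
    """
    rows = table.rows if isinstance(table, ContingencyTable2x2) else tuple(table)
    (a, b), (c, d) = rows
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("Fisher's exact test needs positive margins")
    return float(_scipy_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class BinSet:
    """A random partition of sites into equal-size disjoint bins.

    ``assignments[i]`` holds the site indices of bin i; sites beyond
    ``bin_size * n_bins`` are left unused.
    """

    bin_size: int
    n_bins: int
    assignments: tuple[tuple[int, ...], ...]
    bin_means: tuple[float, ...]
    unused: tuple[int, ...]
    seed: int | None


def make_bins(
    hi_values: Sequence[float],
    bin_size: int,
    n_bins: int,
    seed: int | np.random.Generator | None = None,
) -> BinSet:
    """Randomly distribute sites into `n_bins` bins of `bin_size` each.

    Sampling is uniform without replacement; leftover sites are unused.
    """
    values = np.asarray(hi_values, dtype=float)
    needed = bin_size * n_bins
    if needed > values.size:
        raise ValueError(
            f"need {needed} sites for {n_bins} bins of {bin_size}, have {values.size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(values.size)
    used, unused = order[:needed], order[needed:]
    bins = used.reshape(n_bins, bin_size)
    means = values[bins].mean(axis=1)
    return BinSet(
        bin_size=bin_size,
        n_bins=n_bins,
        assignments=tuple(tuple(int(i) for i in row) for row in bins),
        bin_means=tuple(float(m) for m in means),
        unused=tuple(int(i) for i in unused),
        seed=seed if isinstance(seed, int) else None,
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return _scipy_stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(
    xs: Sequence[float],
    ys: Sequence[float],
    mode: str = "normal",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic W, p).

    W is the sum of the (mid)ranks of `xs` in the pooled sample.  In
    ``"exact"`` mode the p-value is obtained by enumerating all ways of
    assigning the pooled ranks to the first sample (combined n <= 20); in
    ``"normal"`` mode the usual large-sample approximation with tie
    correction and a 0.5 continuity correction is used.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = xs.size, ys.size
    n = n1 + n2
    ranks = _midranks(np.concatenate([xs, ys]))
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n + 1) / 2.0

    if mode == "exact":
        if n > 20:
            raise ValueError("exact enumeration supported for combined n <= 20")
        obs_dev = abs(w - mean_w)
        extreme = total = 0
        for combo in itertools.combinations(range(n), n1):
            ws = ranks[list(combo)].sum()
            total += 1
            if abs(ws - mean_w) >= obs_dev - 1e-12:
                extreme += 1
        return w, extreme / total
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")

    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:  # all pooled values identical
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    p = 2.0 * _scipy_stats.norm.sf(z)
    return w, min(p, 1.0)


@dataclass(frozen=True)
class HiBinComparison:
    """Report of a binned homoplasy comparison between two site classes."""

    x_bins: BinSet
    y_bins: BinSet
    statistic: float
    pvalue: float
    mode: str
    seed: int | None


def compare_hi_bins(
    cam_hi: Sequence[float],
    noncam_hi: Sequence[float],
    bin_size: int = 50,
    n_bins: int = 52,
    n_bins_y: int | None = None,
    seed: int | None = None,
    mode: str = "normal",
) -> HiBinComparison:
    """Bin the two HI samples and rank-sum test the bin means.

    ``n_bins_y`` allows an unequal number of bins for the second class
    (e.g. comparing 52 bins of one class against every available bin of the
    other); it defaults to ``n_bins``.
    """
    if n_bins_y is None:
        n_bins_y = n_bins
    root = np.random.SeedSequence(seed)
    rng_x, rng_y = (np.random.default_rng(s) for s in root.spawn(2))
    x_bins = make_bins(cam_hi, bin_size, n_bins, seed=rng_x)
    y_bins = make_bins(noncam_hi, bin_size, n_bins_y, seed=rng_y)
    statistic, pvalue = wilcoxon_rank_sum(x_bins.bin_means, y_bins.bin_means, mode=mode)
    return HiBinComparison(
        x_bins=x_bins,
        y_bins=y_bins,
        statistic=statistic,
        pvalue=pvalue,
        mode=mode,
        seed=seed,
    )
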