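"""Friedman two-way ANOVA by ranks for regional lesion-distribution tests.

The comparison treats atlas regions as blocks and lesion classes (or
populations) as treatments: within each region the per-class regional
PDs are converted to midranks, and the Friedman chi-square statistic

    chi2_F = (k - 1) * sum_j (R_j - n(k+1)/2)^2
             / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

(tie-corrected form; reduces to 12/(n k (k+1)) sum_j R_j^2 - 3 n (k+1)
without ties) tests whether the k classes share a common regional
distribution. The p-value is exact by permutation when the enumeration
(k!)^n is small enough, otherwise asymptotic chi-square with k-1 df.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image import InputError

EXACT_ENUMERATION_LIMIT = 2_000_000


def midrank(values) -> np.ndarray:
    """Ranks with ties assigned the average (mid) rank."""
    values = np.asarray(values)
    if values.size == 0:
        raise InputError("cannot rank an empty vector")
    return sps.rankdata(values, method="average")


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float
    method: str  # "exact" | "asymptotic"
    tie_corrected: bool
    n_blocks: int
    n_treatments: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "pvalue": self.pvalue,
            "method": self.method,
            "tie_corrected": self.tie_corrected,
            "n_blocks": self.n_blocks,
            "n_treatments": self.n_treatments,
        }


def _statistic_from_ranks(ranks: np.ndarray) -> tuple[float, bool]:
    """Tie-corrected Friedman chi-square from an (n, k) midrank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    numerator = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    denominator = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    has_ties = not np.isclose(denominator, n * k * (k + 1) * (k - 1) / 12.0)
    if denominator <= 0:
        return 0.0, has_ties
    return float(numerator / denominator), has_ties


def _exact_pvalue(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p by convolving per-block rank-sum distributions.

    Under the null every within-block ordering of the observed (mid)ranks
    is equally likely; the statistic depends on the blocks only through
    the column-sum vector and a permutation-invariant tie term, so the
    (k!)^n orderings are enumerated as a distribution over column-sum
    vectors (identical result, far cheaper).
    """
    n, k = ranks.shape
    perms = list(itertools.permutations(range(k)))
    dist: dict[tuple, int] = {tuple([0.0] * k): 1}
    for i in range(n):
        block = ranks[i]
        new: dict[tuple, int] = {}
        for sums, count in dist.items():
            for perm in perms:
                key = tuple(round(s + block[p], 6) for s, p in zip(sums, perm))
                new[key] = new.get(key, 0) + count
        dist = new
    denominator = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    total = sum(dist.values())
    if denominator <= 0:
        return 1.0
    at_least = 0
    for sums, count in dist.items():
        stat = (k - 1) * sum((s - n * (k + 1) / 2.0) ** 2 for s in sums) / denominator
        if stat >= observed - 1e-9:
            at_least += count
    return at_least / total


def friedman_test(table, force_method: str | None = None) -> FriedmanResult:
    """Friedman rank test over an (n blocks x k treatments) value table.

    Accepts an array or DataFrame of raw values (regional PDs); ranks are
    computed within blocks with midranks for ties. All-constant blocks in
    every row yield statistic 0 with a degenerate-data warning.
    """
    values = np.asarray(table, dtype=float)
    if values.ndim != 2:
        raise InputError(f"expected a 2D blocks x treatments table, got shape {values.shape}")
    n, k = values.shape
    if n < 2 or k < 2:
        raise InputError(f"need n >= 2 blocks and k >= 2 treatments, got {values.shape}")
    ranks = np.vstack([midrank(row) for row in values])
    statistic, tie_corrected = _statistic_from_ranks(ranks)
    denominator = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    if denominator <= 0:
        warnings.warn("degenerate data: every treatment tied in every block", stacklevel=2)
        return FriedmanResult(0.0, k - 1, 1.0, "degenerate", tie_corrected, n, k)

    use_exact = math.factorial(k) ** n <= EXACT_ENUMERATION_LIMIT
    if force_method is not None:
        use_exact = force_method == "exact"
    if use_exact:
        pvalue = _exact_pvalue(ranks, statistic)
        method = "exact"
    else:
        pvalue = float(sps.chi2.sf(statistic, k - 1))
        method = "asymptotic"
    return FriedmanResult(statistic, k - 1, pvalue, method, tie_corrected, n, k)


def blocked_ranks(values) -> np.ndarray:
    """Within-block midrank matrix for an (n, k) table (diagnostic view)."""
    values = np.asarray(values, dtype=float)
    return np.vstack([midrank(row) for row in values])


def compare_lesion_distributions(
    table: pd.DataFrame,
    treatments: list[str],
    average_laterality: bool = True,
) -> dict:
    """Friedman comparison of lesion classes over the regional PD table.

    Blocks are regions; by default left/right values of a paired region
    are averaged into one block, otherwise each (region, laterality) row
    stays a separate block.
    """
    missing = [t for t in treatments if t not in table.columns]
    if missing:
        raise InputError(f"region table lacks lesion-class columns: {missing}")
    if average_laterality:
        blocks = table.groupby("region", sort=True)[treatments].mean()
    else:
        blocks = table.set_index(["region", "laterality"])[treatments]
    result = friedman_test(blocks.to_numpy())
    return {
        "treatments": list(treatments),
        "blocks": [str(i) for i in blocks.index.tolist()],
        "average_laterality": average_laterality,
        **result.to_dict(),
    }
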