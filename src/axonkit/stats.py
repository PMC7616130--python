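"""Nonparametric group statistics.

Replicates are pooled (every observation is one datapoint); conditions are
compared with a Kruskal–Wallis omnibus test followed by Dunn rank-sum
z-tests for all pairs with Bonferroni correction; looping frequencies are
compared with Fisher's exact test.  Significance tiers follow the usual
strict cutoffs: * p < 0.05, ** p < 0.01, *** p < 0.001, **** p < 0.0001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "TestResult",
    "ContingencyTable2x2",
    "pool_replicates",
    "kruskal_wallis",
    "pairwise_bonferroni",
    "fisher_exact_2x2",
    "significance_tier",
    "run_metric_tests",
]


@dataclass
class GroupData:
    label: str
    values: np.ndarray
    replicate_ids: np.ndarray | None = None
    pooled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} has no observations")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if self.replicate_ids.shape != self.values.shape:
                raise ValueError("replicate ids must align with values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class TestResult:
    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float
    tier: str


@dataclass
class ContingencyTable2x2:
    """Counts a, b / c, d: rows are outcomes (e.g. looping / non-looping),
    columns are the two conditions."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be nonnegative integers")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], int)


def pool_replicates(label: str, replicate_values) -> GroupData:
    """Concatenate per-replicate observation lists into one pooled group,
    retaining the replicate index of each observation for audit."""
    lists = [np.asarray(v, float) for v in replicate_values]
    if not lists or all(v.size == 0 for v in lists):
        raise ValueError("no observations in any replicate")
    values = np.concatenate([v for v in lists if v.size])
    reps = np.concatenate([np.full(v.size, i) for i, v in enumerate(lists) if v.size])
    return GroupData(label=label, values=values, replicate_ids=reps, pooled=True)


def significance_tier(p: float) -> str:
    """Map a p-value to the study's tier string (strict thresholds)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def kruskal_wallis(groups: list[GroupData]) -> TestResult:
    """Kruskal–Wallis H (tie-corrected) across k groups; p from the χ²
    approximation with k−1 df.  All-identical data yields H = 0, p = 1."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [g.values for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("omnibus", 0.0, 1.0, 1.0, "n.s.")
    h, p = sps.kruskal(*arrays)
    return TestResult("omnibus", float(h), float(p), float(p),
                      significance_tier(p))


def _dunn_pair(groups: list[GroupData], i: int, j: int) -> tuple[float, float]:
    """Dunn z-test for pair (i, j) on the pooled midranks with tie correction."""
    pooled = np.concatenate([g.values for g in groups])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    bounds = np.cumsum([0] + [g.n for g in groups])
    mean_ranks = [ranks[bounds[k]:bounds[k + 1]].mean() for k in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / groups[i].n
                                                         + 1.0 / groups[j].n)
    if var <= 0:
        return 0.0, 1.0
    z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def pairwise_bonferroni(groups: list[GroupData],
                        method: str = "dunn") -> list[TestResult]:
    """All k(k−1)/2 pairwise comparisons, Bonferroni-adjusted.

    ``method='dunn'``: z-tests on the joint ranking (the classical
    Kruskal–Wallis post-hoc); ``method='mannwhitney'``: independent
    two-sample rank-sum tests per pair.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    results = []
    for i, j in pairs:
        name = f"{groups[i].label} vs {groups[j].label}"
        if np.all(groups[i].values == groups[i].values[0]) and np.all(
                groups[j].values == groups[i].values[0]):
            stat, p = 0.0, 1.0
        elif method == "dunn":
            stat, p = _dunn_pair(groups, i, j)
        elif method == "mannwhitney":
            stat, p = sps.mannwhitneyu(groups[i].values, groups[j].values,
                                       alternative="two-sided")
            stat, p = float(stat), float(p)
        else:
            raise ValueError(f"unknown method {method!r}")
        p_adj = min(1.0, m * p)
        results.append(TestResult(name, stat, p, p_adj, significance_tier(p_adj)))
    return results


def fisher_exact_2x2(table: ContingencyTable2x2,
                     alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table (two-sided by default: sum of
    hypergeometric probabilities no larger than the observed table's)."""
    arr = table.array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin: test undefined")
    odds, p = sps.fisher_exact(arr, alternative=alternative)
    return TestResult("fisher", float(odds), float(p), float(p),
                      significance_tier(p))


def run_metric_tests(df: pd.DataFrame, value_col: str,
                     group_col: str = "condition",
                     method: str = "dunn") -> pd.DataFrame:
    """Omnibus + pairwise results for one metric of a long-format table."""
    groups = [GroupData(str(label), sub[value_col].dropna().to_numpy())
              for label, sub in df.groupby(group_col, sort=False)]
    rows = []
    omni = kruskal_wallis(groups)
    rows.append({"metric": value_col, "comparison": omni.comparison,
                 "statistic": omni.statistic, "p_raw": omni.p_raw,
                 "p_adjusted": omni.p_adjusted, "tier": omni.tier})
    for r in pairwise_bonferroni(groups, method=method):
        rows.append({"metric": value_col, "comparison": r.comparison,
                     "statistic": r.statistic, "p_raw": r.p_raw,
                     "p_adjusted": r.p_adjusted, "tier": r.tier})
    return pd.DataFrame(rows)
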