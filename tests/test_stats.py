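"""Group statistics: Kruskal-Wallis, Dunn-Bonferroni, Fisher's exact, tiers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from axonkit.stats import (ContingencyTable2x2, GroupData, fisher_exact_2x2,
                           kruskal_wallis, pairwise_bonferroni,
                           pool_replicates, run_metric_tests,
                           significance_tier)


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


# ---------------------------------------------------------------------------
# Pooling


def test_pool_replicates_concatenates():
    g = pool_replicates("ctrl", [[1.0, 2, 3], [4.0, 5, 6, 7]])
    assert g.n == 7
    assert g.pooled
    assert list(np.unique(g.replicate_ids)) == [0, 1]
    assert (g.replicate_ids == 1).sum() == 4


def test_pool_single_replicate_identity():
    g = pool_replicates("x", [[1.0, 2.0]])
    assert np.array_equal(g.values, [1.0, 2.0])


def test_pool_empty_errors():
    with pytest.raises(ValueError):
        pool_replicates("x", [[], []])


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def test_kw_symmetric_ranks():
    groups = [GroupData("a", [1, 6]), GroupData("b", [2, 5]),
              GroupData("c", [3, 4])]
    res = kruskal_wallis(groups)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_raw == pytest.approx(1.0)


def test_kw_degenerate_identical_data():
    groups = [GroupData("a", [2.0, 2.0]), GroupData("b", [2.0, 2.0])]
    res = kruskal_wallis(groups)
    assert res.p_raw == 1.0 and res.tier == "n.s."


def test_kw_power_on_shifted_groups(rng):
    """Two groups of 30 shifted by 2 SD: p < 0.001 nearly always."""
    hits = 0
    for _ in range(100):
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        res = kruskal_wallis([GroupData("a", a), GroupData("b", b)])
        hits += res.p_raw < 1e-3
    assert hits >= 99


def test_kw_invariant_under_monotone_transform(rng):
    a, b, c = (rng.normal(i, 1, 15) for i in range(3))
    groups = [GroupData("a", a), GroupData("b", b), GroupData("c", c)]
    h1 = kruskal_wallis(groups).statistic
    tgroups = [GroupData(g.label, np.exp(g.values)) for g in groups]
    h2 = kruskal_wallis(tgroups).statistic
    assert h1 == pytest.approx(h2, rel=1e-12)


def test_kw_type_one_error_calibration(rng):
    """Null rejection rate at alpha=0.05 stays near 0.05."""
    n_sim = 800
    rej = 0
    for _ in range(n_sim):
        groups = [GroupData(str(i), rng.normal(0, 1, 15)) for i in range(3)]
        rej += kruskal_wallis(groups).p_raw < 0.05
    rate = rej / n_sim
    assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_sim) + 0.005


# ---------------------------------------------------------------------------
# Pairwise Bonferroni


def test_bonferroni_arithmetic():
    assert min(1.0, 6 * 0.01) == pytest.approx(0.06)
    groups = [GroupData(str(i), np.arange(5) + 3 * i) for i in range(4)]
    res = pairwise_bonferroni(groups)
    assert len(res) == 6
    for r in res:
        assert r.p_adjusted >= r.p_raw
        assert r.p_adjusted <= 1.0
        assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw))


def test_pairwise_identical_groups():
    groups = [GroupData("a", [1.0] * 5), GroupData("b", [1.0] * 5)]
    res = pairwise_bonferroni(groups)
    assert all(r.p_adjusted == 1.0 for r in res)


def test_pairwise_mannwhitney_alternative(rng):
    groups = [GroupData("a", rng.normal(0, 1, 20)),
              GroupData("b", rng.normal(3, 1, 20))]
    res = pairwise_bonferroni(groups, method="mannwhitney")
    assert res[0].p_adjusted < 0.01


# ---------------------------------------------------------------------------
# Fisher's exact


def test_fisher_balanced_table():
    res = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
    assert res.p_raw == pytest.approx(1.0)


def test_fisher_extreme_table_matches_enumeration():
    res = fisher_exact_2x2(ContingencyTable2x2(0, 10, 10, 0))
    assert res.p_raw == pytest.approx(fisher_enumeration_oracle(0, 10, 10, 0),
                                      rel=1e-9)


def test_fisher_transpose_symmetry(rng):
    for _ in range(20):
        a, b, c, d = rng.integers(1, 12, 4)
        p1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_raw
        p2 = fisher_exact_2x2(ContingencyTable2x2(a, c, b, d)).p_raw
        assert p1 == pytest.approx(p2, rel=1e-12)


def test_fisher_matches_enumeration_small_tables():
    for a, b, c, d in itertools.product(range(7), repeat=4):
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_raw
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d),
                                  rel=1e-8, abs=1e-12)


def test_fisher_zero_margin_errors():
    with pytest.raises(ValueError, match="margin"):
        fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))


# ---------------------------------------------------------------------------
# Tiers


@pytest.mark.parametrize("p,tier", [
    (0.03, "*"), (0.20, "n.s."), (0.0005, "***"),
    (0.05, "n.s."), (0.01, "*"), (0.001, "**"), (0.0001, "***"),
    (0.00009, "****"), (0.0, "****"), (1.0, "n.s."),
])
def test_tier_mapping(p, tier):
    assert significance_tier(p) == tier


_SEVERITY = {"n.s.": 0, "*": 1, "**": 2, "***": 3, "****": 4}


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
@settings(derandomize=True, max_examples=200)
def test_tier_monotone_in_p(p1, p2):
    """A smaller p-value never gets a less significant tier."""
    if p1 > p2:
        p1, p2 = p2, p1
    assert _SEVERITY[significance_tier(p1)] >= _SEVERITY[significance_tier(p2)]


@given(st.floats(0.0, 1.0), st.integers(1, 20))
@settings(derandomize=True, max_examples=200)
def test_bonferroni_bounds(p, m):
    """Bonferroni adjustment never drops below the raw p and caps at 1."""
    p_adj = min(1.0, m * p)
    assert p <= p_adj <= 1.0


def test_tier_rejects_invalid():
    with pytest.raises(ValueError):
        significance_tier(1.5)
    with pytest.raises(ValueError):
        significance_tier(-0.1)


def test_run_metric_tests_table(rng):
    import pandas as pd
    df = pd.DataFrame({
        "condition": ["a"] * 20 + ["b"] * 20 + ["c"] * 20,
        "val": np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                               rng.normal(4, 1, 20)]),
    })
    res = run_metric_tests(df, "val")
    assert len(res) == 1 + 3
    omni = res[res.comparison == "omnibus"].iloc[0]
    assert omni.p_raw < 0.001
    sig = res[res.comparison.str.contains("c")]
    assert (sig.p_adjusted < 0.05).all()
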