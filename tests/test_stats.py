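"""Exact test statistics against closed forms, enumeration and scipy."""

import math

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_mw_tails
from orcevo.reconcile import EventMap
from orcevo.stats import (
    ContingencyTable2x2,
    enrichment_test,
    fisher_one_tailed,
    hypergeom_logpmf,
    hypergeom_support,
    mann_whitney,
    midranks,
    spearman,
)
from orcevo.trees import LineageSet


# ---------------------------------------------------------------------------
# Fisher / hypergeometric
# ---------------------------------------------------------------------------

def test_fisher_reproduces_parasite_loss_pvalue():
    """41/69 losses in 83/263 lineages -> the published one-tailed P."""
    res = fisher_one_tailed(ContingencyTable2x2(41, 28, 83, 180))
    assert res.pvalue == pytest.approx(2.43e-5, rel=0.05)
    assert res.extras["table"] == [[41, 28], [83, 180]]


def test_fisher_derived_example():
    # exhaustive enumeration over tables with margins (4,4)/(4,4): P = 17/70
    res = fisher_one_tailed(ContingencyTable2x2(3, 1, 1, 3))
    assert res.pvalue == pytest.approx(17 / 70, abs=1e-12)


def test_fisher_certain_tail_is_exactly_one():
    assert fisher_one_tailed(ContingencyTable2x2(0, 5, 5, 5)).pvalue == 1.0


def test_fisher_all_zero_rejected():
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)


@pytest.mark.parametrize("N,K,n", [(332, 124, 69), (20, 5, 7), (11, 11, 4), (9, 3, 8)])
def test_hypergeom_pmf_sums_to_one(N, K, n):
    total = sum(math.exp(hypergeom_logpmf(k, N, K, n)) for k in hypergeom_support(N, K, n))
    assert abs(total - 1.0) < 1e-12


def test_fisher_matches_scipy_and_monotone_in_a():
    rng = np.random.default_rng(2)
    for _ in range(50):
        a, b, c, d = (int(v) for v in rng.integers(0, 30, size=4))
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        mine = fisher_one_tailed(ContingencyTable2x2(a, b, c, d)).pvalue
        ref = ss.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert mine == pytest.approx(ref, rel=1e-9)
    # tail P non-increasing as the observed cell grows with margins fixed
    ps = []
    for a in range(0, 6):
        # margins: row1 = 5, col1 = 5, N = 15
        ps.append(fisher_one_tailed(ContingencyTable2x2(a, 5 - a, 5 - a, 5 + a)).pvalue)
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mw_simple_exact_example():
    res = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
    assert res.pvalue == pytest.approx(1 / 20)
    assert res.method == "exact" and res.statistic == 0


def test_mw_identical_samples_two_sided():
    res = mann_whitney([1, 2, 3], [1, 2, 3], alternative="two-sided")
    assert res.pvalue == 1.0


def test_mw_exact_matches_enumeration_all_small_sizes():
    """DP-exact tail equals brute-force pair-counting enumeration for every
    pair of sample sizes up to 7 (tie-free)."""
    rng = np.random.default_rng(1)
    for n1 in range(1, 8):
        for n2 in range(1, 8):
            pooled = rng.permutation(n1 + n2) + rng.random(n1 + n2) * 0.1
            x, y = list(pooled[:n1]), list(pooled[n1:])
            res_le = mann_whitney(x, y, alternative="less", method="exact")
            res_ge = mann_whitney(x, y, alternative="greater", method="exact")
            p_le, p_ge = brute_force_mw_tails(x, y, res_le.statistic)
            assert res_le.pvalue == pytest.approx(p_le, abs=1e-12)
            assert res_ge.pvalue == pytest.approx(p_ge, abs=1e-12)


def test_mw_exact_with_ties_matches_enumeration():
    x, y = [1, 1, 2], [2, 3, 3]
    res = mann_whitney(x, y, alternative="less", method="exact")
    p_le, _ = brute_force_mw_tails(x, y, res.statistic)
    assert res.pvalue == pytest.approx(p_le, abs=1e-12)


def test_mw_approximation_close_to_scipy():
    rng = np.random.default_rng(9)
    x = list(rng.normal(0, 1, 30))
    y = list(rng.normal(0.8, 1, 25))
    mine = mann_whitney(x, y, alternative="two-sided")
    ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert mine.method == "normal-approximation"
    assert mine.statistic == ref.statistic
    assert mine.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


def test_mw_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone_extremes_and_example():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
    assert spearman([1, 2, 3, 4], [5, 4, 3, 2]).statistic == -1.0
    assert spearman([1, 2, 3, 4], [2, 1, 4, 3]).statistic == pytest.approx(0.6)


def test_spearman_is_pearson_on_midranks_and_matches_scipy():
    rng = np.random.default_rng(4)
    for _ in range(25):
        x = list(rng.integers(0, 10, 15).astype(float))  # ties likely
        y = list(rng.normal(size=15))
        if len(set(x)) == 1:
            continue
        mine = spearman(x, y).statistic
        pearson_on_ranks = np.corrcoef(ss.rankdata(x), ss.rankdata(y))[0, 1]
        assert mine == pytest.approx(pearson_on_ranks, abs=1e-12)
        assert mine == pytest.approx(ss.spearmanr(x, y).statistic, abs=1e-12)


@given(st.permutations(list(range(8))))
@settings(max_examples=100, deadline=None)
def test_spearman_invariant_under_monotone_transform(perm):
    x = [float(v) for v in perm]
    y = [float((v * 7) % 8) for v in perm]
    base = spearman(x, y).statistic
    assert spearman([math.exp(v) for v in x], y).statistic == pytest.approx(base)
    assert spearman(x, [v**3 for v in y]).statistic == pytest.approx(base)


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_midranks_average_ties():
    assert midranks([10, 20, 20, 30]) == [1.0, 2.5, 2.5, 4.0]


# ---------------------------------------------------------------------------
# Enrichment wrapper
# ---------------------------------------------------------------------------

def _lineage_set(n, n_class):
    ids = tuple(f"L{i}" for i in range(n))
    return LineageSet(ids, frozenset(ids[:n_class]), frozenset())


def test_enrichment_builds_published_table():
    lineages = _lineage_set(263, 83)
    emap = EventMap(family=None, root_count=0)
    # 41 losses inside the class, 28 outside
    for i in range(41):
        emap.losses[f"L{i}"] = 1
    for i in range(83, 111):
        emap.losses[f"L{i}"] = 1
    res = enrichment_test(emap, lineages, "loss", "parasitic")
    assert res.extras["table"] == [[41, 28], [83, 180]]
    assert res.pvalue == pytest.approx(2.43e-5, rel=0.05)


def test_enrichment_extreme_and_proportional():
    lineages = _lineage_set(40, 20)
    concentrated = EventMap(family=None, root_count=0,
                            losses={f"L{i}": 1 for i in range(12)})
    assert enrichment_test(concentrated, lineages, "loss", "parasitic").pvalue < 0.05
    # events split proportionally to class sizes are never "enriched"
    rng = np.random.default_rng(0)
    for _ in range(100):
        total = int(rng.integers(20, 120))
        lineages263 = _lineage_set(263, 83)
        a = round(total * 83 / 263)
        emap = EventMap(family=None, root_count=0)
        for i in range(a):
            emap.losses[f"L{i}"] = emap.losses.get(f"L{i}", 0) + 1
        for i in range(83, 83 + (total - a)):
            emap.losses[f"L{i}"] = emap.losses.get(f"L{i}", 0) + 1
        assert enrichment_test(emap, lineages263, "loss", "parasitic").pvalue >= 0.3


def test_enrichment_empty_class_rejected():
    lineages = LineageSet(("L0", "L1"), frozenset(), frozenset())
    emap = EventMap(family=None, root_count=0, losses={"L0": 1})
    with pytest.raises(ValueError, match="empty lineage class"):
        enrichment_test(emap, lineages, "loss", "parasitic")
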