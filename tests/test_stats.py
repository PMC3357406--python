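"""Statistical primitives against independent oracles.

Each test either freezes a hand-derived value, enumerates the exact null
distribution with independent arithmetic (fractions / itertools), or
cross-checks against an established library implementation.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu as scipy_mw
from scipy.stats import ttest_ind

from lungdiverge.stats import (
    DegenerateDataError,
    bh_adjust,
    fisher_exact_3x2,
    logrank_test,
    mann_whitney,
    roc_auc,
    welch_t,
)


# ---------------------------------------------------------------------------
# Fisher 3x2
# ---------------------------------------------------------------------------

def fisher_3x2_fraction_oracle(table) -> Fraction:
    """Exact-rational enumeration over all tables with the same margins."""
    a = np.asarray(table, dtype=int)
    rows = a.sum(axis=1)
    c1 = int(a[:, 0].sum())
    n = int(a.sum())

    def prob(a1, a2, a3):
        return Fraction(
            math.comb(rows[0], a1) * math.comb(rows[1], a2) * math.comb(rows[2], a3),
            math.comb(n, c1),
        )

    obs = prob(a[0, 0], a[1, 0], a[2, 0])
    total = Fraction(0)
    for a1 in range(min(rows[0], c1) + 1):
        for a2 in range(min(rows[1], c1 - a1) + 1):
            a3 = c1 - a1 - a2
            if 0 <= a3 <= rows[2]:
                p = prob(a1, a2, a3)
                if p <= obs:
                    total += p
    return total


@pytest.mark.parametrize(
    "table, expected",
    [
        ([[0, 0], [0, 0], [4, 6]], 1.0),  # single admissible table
        ([[2, 0], [0, 2], [0, 0]], 1 / 3),  # enumeration over 3 tables
        ([[1, 3], [3, 1], [0, 0]], 34 / 70),  # reduces to 2x2 hypergeometric
    ],
)
def test_fisher_frozen_examples(table, expected):
    assert fisher_exact_3x2(table).p == pytest.approx(expected, abs=1e-12)


def test_fisher_matches_rational_enumeration_exhaustively():
    """Every 3x2 table with total count <= 8 agrees with the exact-rational
    oracle to 1e-12."""
    worst = 0.0
    for total in range(1, 9):
        for cells in itertools.product(range(total + 1), repeat=6):
            if sum(cells) != total:
                continue
            table = np.asarray(cells).reshape(3, 2)
            got = fisher_exact_3x2(table).p
            want = float(fisher_3x2_fraction_oracle(table))
            worst = max(worst, abs(got - want))
    assert worst < 1e-12


def test_fisher_rejects_degenerate_input():
    with pytest.raises(DegenerateDataError):
        fisher_exact_3x2([[0, 0], [0, 0], [0, 0]])
    with pytest.raises(ValueError):
        fisher_exact_3x2([[1, -1], [0, 0], [0, 0]])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_stepup_oracle(pvals, m=None):
    """Literal step-up definition: q_(i) = min over j >= i of p_(j)*m/j."""
    m = m or len(pvals)
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    out = [0.0] * len(pvals)
    for rank, i in enumerate(order, start=1):
        q = min(
            min(pvals[j] * m / (order.index(j) + 1) for j in order[rank - 1 :]), 1.0
        )
        out[i] = q
    return out


@pytest.mark.parametrize(
    "pvals, expected",
    [
        ([0.5], [0.5]),
        ([0.01, 0.04, 0.03, 0.02], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.1, 0.9], [0.015, 0.15, 0.9]),
    ],
)
def test_bh_frozen_examples(pvals, expected):
    assert bh_adjust(pvals) == pytest.approx(expected)


@settings(deadline=None, max_examples=200)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6)
)
def test_bh_matches_stepup_oracle(pvals):
    assert bh_adjust(pvals) == pytest.approx(bh_stepup_oracle(pvals), abs=1e-12)


def test_bh_family_size_scales_singletons():
    # one observed p corrected within a declared family of 10 tests
    assert bh_adjust([0.004], family_size=10) == pytest.approx([0.04])
    with pytest.raises(ValueError):
        bh_adjust([0.1, 0.2], family_size=1)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 30))
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mw_enumeration_oracle(x, y, tail):
    """p by complete enumeration of group assignments of the pooled sample."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(group):
        rest = pooled.copy()
        for v in group:
            rest.remove(v)
        return sum(1 for a in group for b in rest if a > b) + 0.5 * sum(
            1 for a in group for b in rest if a == b
        )

    u_obs = u_of(list(x))
    us = [u_of(list(c)) for c in itertools.combinations(pooled, n)]
    if tail == "one_sided_greater":
        hits = sum(1 for u in us if u >= u_obs - 1e-9)
    elif tail == "one_sided_less":
        hits = sum(1 for u in us if u <= u_obs + 1e-9)
    else:
        raise NotImplementedError
    return hits / len(us)


@pytest.mark.parametrize(
    "x, y, tail, expected",
    [
        ((5, 6, 7), (1, 2, 3), "one_sided_greater", 1 / 20),
        ((2, 4), (1, 3), "one_sided_greater", 1 / 3),
        ((1, 2), (3, 4), "one_sided_greater", 1.0),
    ],
)
def test_mw_frozen_examples(x, y, tail, expected):
    assert mann_whitney(x, y, tail).p == pytest.approx(expected)


def test_mw_exact_branch_matches_enumeration():
    """All tie-free splits with combined n <= 8 match complete enumeration."""
    rng = np.random.default_rng(11)
    for n, m in [(1, 1), (2, 2), (2, 3), (3, 3), (3, 4), (4, 4), (2, 6), (1, 7)]:
        for _ in range(5):
            vals = rng.permutation(np.arange(1, n + m + 1, dtype=float))
            x, y = vals[:n], vals[n:]
            for tail in ("one_sided_greater", "one_sided_less"):
                assert mann_whitney(x, y, tail).p == pytest.approx(
                    mw_enumeration_oracle(x, y, tail)
                )


def test_mw_exact_tail_complement_identity():
    """On the exact branch p(greater) + p(less) - P(U = u_obs) = 1."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        vals = rng.permutation(np.arange(1.0, 9.0))
        x, y = vals[:4], vals[4:]
        pg = mann_whitney(x, y, "one_sided_greater").p
        pl = mann_whitney(x, y, "one_sided_less").p
        pe = mw_enumeration_oracle(x, y, "one_sided_greater") + mw_enumeration_oracle(
            x, y, "one_sided_less"
        ) - 1.0  # = P(U = u_obs)
        assert pg + pl - pe == pytest.approx(1.0)


def test_mw_asymptotic_branch_matches_scipy():
    rng = np.random.default_rng(5)
    x = rng.normal(0.3, 1.0, 20)
    y = rng.normal(0.0, 1.0, 25)
    ours = mann_whitney(x, y, "one_sided_greater")
    ref = scipy_mw(x, y, alternative="greater", method="asymptotic")
    assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)
    assert ours.statistic == pytest.approx(ref.statistic)
    # with ties
    xt = np.round(x, 0)
    yt = np.round(y, 0)
    ours_t = mann_whitney(xt, yt, "two_sided")
    ref_t = scipy_mw(xt, yt, alternative="two-sided", method="asymptotic")
    assert ours_t.p == pytest.approx(ref_t.pvalue, rel=1e-6)


def test_mw_all_tied_returns_maximal_p():
    assert mann_whitney([1.0] * 15, [1.0] * 15, "two_sided").p == 1.0


def test_mw_empty_group_raises():
    with pytest.raises(DegenerateDataError):
        mann_whitney([], [1.0], "two_sided")


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def test_welch_frozen_examples():
    res = welch_t((1, 2, 3), (1, 2, 3), "one_sided_greater")
    assert res.statistic == 0.0 and res.p == pytest.approx(0.5)
    res = welch_t((1, 2), (3, 4), "one_sided_less")
    assert res.statistic == pytest.approx(-2.828, abs=1e-3)
    assert res.p == pytest.approx(0.0528, abs=1e-4)
    with pytest.raises(DegenerateDataError):
        welch_t((1, 1), (1, 1))


def test_welch_matches_scipy():
    rng = np.random.default_rng(9)
    x = rng.normal(0.0, 1.0, 12)
    y = rng.normal(0.5, 2.0, 8)
    ours = welch_t(x, y, "two_sided")
    ref = ttest_ind(x, y, equal_var=False)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.p == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_hand_computed_example():
    """Events at t=1,2 in A and t=3,4 in B: O=2, E=5/6, V=17/36 gives
    chi-square 49/17 ~ 2.882, p ~ 0.090."""
    res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
    assert res.statistic == pytest.approx(49 / 17, abs=1e-9)
    assert res.p == pytest.approx(0.0896, abs=1e-3)


def test_logrank_trivial_cases():
    # identical survival in both groups -> 0, p = 1
    res = logrank_test([1, 2, 1, 2], [1, 1, 1, 1], ["A", "A", "B", "B"])
    assert res.statistic == pytest.approx(0.0) and res.p == pytest.approx(1.0)
    # all censored -> 0, p = 1
    res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])
    assert res.statistic == 0.0 and res.p == 1.0


def test_logrank_label_swap_invariance_and_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(21)
    times = rng.exponential(10, 40)
    events = rng.integers(0, 2, 40)
    groups = np.array(["A"] * 20 + ["B"] * 20)
    a = logrank_test(times, events, groups)
    b = logrank_test(times, events, np.where(groups == "A", "B", "A"))
    assert a.statistic == pytest.approx(b.statistic)
    ref = ll_logrank(
        times[:20], times[20:], events[:20], events[20:]
    )
    assert a.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
    assert a.p == pytest.approx(ref.p_value, rel=1e-9)


# ---------------------------------------------------------------------------
# ROC AUC
# ---------------------------------------------------------------------------

def test_roc_examples_and_sklearn():
    from sklearn.metrics import roc_auc_score

    assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5
    assert roc_auc([0.35, 0.8, 0.1, 0.4], [1, 1, 0, 0]) == 0.75
    rng = np.random.default_rng(13)
    scores = rng.normal(size=50)
    labels = rng.integers(0, 2, 50)
    if labels.sum() in (0, 50):
        labels[0] = 1 - labels[0]
    assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


@settings(deadline=None, max_examples=100)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=4,
        max_size=20,
        unique=True,
    )
)
def test_roc_negation_symmetry(scores):
    labels = [i % 2 for i in range(len(scores))]
    assert roc_auc(scores, labels) + roc_auc([-s for s in scores], labels) == pytest.approx(1.0)


def test_roc_single_class_raises():
    with pytest.raises(DegenerateDataError):
        roc_auc([1, 2, 3], [1, 1, 1])
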