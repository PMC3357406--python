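"""Statistical primitives used throughout the pipeline.

Every test here returns a :class:`TestResult`; p-values are exact where an
exact computation is cheap (Fisher 3x2 always; Mann-Whitney for small
tie-free samples) and documented approximations elsewhere.  Each primitive
is verified in the test suite against an independent oracle (full
enumeration, closed form, or an established library).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist

Tail = Literal["one_sided_greater", "one_sided_less", "two_sided"]

#: relative tolerance when deciding whether an enumerated table is "at most
#: as probable" as the observed one (two-sided exact-test convention).
PROB_TOL = 1e-12

#: largest combined sample size for which the Mann-Whitney exact branch
#: runs (tie-free data only); the count recurrence stays cheap well past
#: the size where the normal approximation becomes adequate.
MW_EXACT_MAX_N = 30


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    __test__ = False  # not a pytest class despite the name

    statistic: float
    p: float
    tail: Tail

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.p <= 1 + 1e-12):
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        object.__setattr__(self, "p", float(min(max(self.p, 0.0), 1.0)))


class DegenerateDataError(ValueError):
    """Raised when a test is undefined for the supplied data."""


# ---------------------------------------------------------------------------
# Fisher exact test on a 3x2 table
# ---------------------------------------------------------------------------

def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


@lru_cache(maxsize=200_000)
def _fisher_3x2_cached(counts: tuple[int, ...]) -> float:
    a = np.asarray(counts, dtype=np.int64).reshape(3, 2)
    row = a.sum(axis=1)  # r1, r2, r3
    col = a.sum(axis=0)  # c1, c2
    n = int(a.sum())
    c1 = int(col[0])

    # A table with these margins is determined by its first column
    # (a1, a2, a3): a1 + a2 + a3 = c1, 0 <= ai <= ri.  Under the null the
    # probability is multivariate hypergeometric:
    #   P = C(r1,a1) C(r2,a2) C(r3,a3) / C(n, c1).
    a1 = np.arange(min(int(row[0]), c1) + 1)
    a2 = np.arange(min(int(row[1]), c1) + 1)
    g1, g2 = np.meshgrid(a1, a2, indexing="ij")
    g3 = c1 - g1 - g2
    valid = (g3 >= 0) & (g3 <= int(row[2]))

    logp = (
        _log_binom(int(row[0]), g1)
        + _log_binom(int(row[1]), g2)
        + np.where(valid, _log_binom(int(row[2]), np.where(valid, g3, 0)), -np.inf)
        - _log_binom(n, c1)
    )
    logp = np.where(valid, logp, -np.inf)

    log_obs = (
        _log_binom(int(row[0]), int(a[0, 0]))
        + _log_binom(int(row[1]), int(a[1, 0]))
        + _log_binom(int(row[2]), int(a[2, 0]))
        - _log_binom(n, c1)
    )

    # two-sided: sum probabilities of all tables at most as probable as the
    # observed one, with a relative tolerance on the comparison
    include = logp <= log_obs + math.log1p(PROB_TOL)
    p = float(np.exp(logp[include & valid]).sum())
    return min(p, 1.0)


def fisher_exact_3x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 3x2 contingency table.

    Rows are the three alteration categories (gain/neutral/loss, or
    hyper/unchanged/hypo), columns the two subtype groups.  The p-value is
    the total null (multivariate hypergeometric, fixed margins) probability
    of every table at most as probable as the observed one.
    """
    a = np.asarray(table, dtype=np.int64)
    if a.shape != (3, 2):
        raise ValueError(f"expected a 3x2 table, got shape {a.shape}")
    if (a < 0).any():
        raise ValueError("negative counts in contingency table")
    if a.sum() == 0:
        raise DegenerateDataError("all-zero contingency table")
    p = _fisher_3x2_cached(tuple(int(x) for x in a.ravel()))
    return TestResult(statistic=float(a[0, 0]), p=p, tail="two_sided")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    ``family_size`` makes an explicit correction family possible when the
    supplied list is a subset of the tests actually performed (e.g. a
    correction "based on the number of distinct regions"); it must be at
    least ``len(pvalues)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size smaller than number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank assignments with each U value, for tie-free samples.

    Classic recurrence c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u) over the
    null distribution of U = sum over pairs of 1[x > y]; the total over all
    u is C(n+m, n).
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n, m - 1)  # length n*(m-1) + 1
    b = _u_counts(n - 1, m)  # length (n-1)*m + 1
    out = []
    for u in range(n * m + 1):
        v = a[u] if u < len(a) else 0
        if 0 <= u - m < len(b):
            v += b[u - m]
        out.append(v)
    return tuple(out)


def _mw_exact_p(u: float, n: int, m: int, tail: Tail) -> float:
    counts = np.asarray(_u_counts(n, m), dtype=float)
    total = counts.sum()
    u_int = int(round(u))
    if tail == "one_sided_greater":
        return float(counts[u_int:].sum() / total)
    if tail == "one_sided_less":
        return float(counts[: u_int + 1].sum() / total)
    p_lo = counts[: u_int + 1].sum() / total
    p_hi = counts[u_int:].sum() / total
    return float(min(1.0, 2 * min(p_lo, p_hi)))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], tail: Tail = "two_sided"
) -> TestResult:
    """Mann-Whitney U test; statistic is U for the first group.

    Exact enumeration when the combined sample is at most
    :data:`MW_EXACT_MAX_N` and tie-free; otherwise the normal approximation
    with tie-corrected variance and a 0.5 continuity correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise DegenerateDataError("both groups must be nonempty")
    n, m = xa.size, ya.size
    combined = np.concatenate([xa, ya])
    # midranks
    order = np.argsort(combined, kind="stable")
    ranks = np.empty(n + m, dtype=float)
    sorted_vals = combined[order]
    i = 0
    while i < n + m:
        j = i
        while j + 1 < n + m and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    has_ties = len(np.unique(combined)) < n + m
    if n + m <= MW_EXACT_MAX_N and not has_ties:
        return TestResult(statistic=u, p=_mw_exact_p(u, n, m, tail), tail=tail)

    mean_u = n * m / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_u = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var_u <= 0:
        # every observation tied: no evidence either way
        return TestResult(statistic=u, p=1.0, tail=tail)
    sd = math.sqrt(var_u)
    if tail == "one_sided_greater":
        z = (u - mean_u - 0.5) / sd
        p = float(_norm.sf(z))
    elif tail == "one_sided_less":
        z = (u - mean_u + 0.5) / sd
        p = float(_norm.cdf(z))
    else:
        z = (abs(u - mean_u) - 0.5) / sd
        p = float(2 * _norm.sf(max(z, 0.0)))
    return TestResult(statistic=u, p=min(p, 1.0), tail=tail)


# ---------------------------------------------------------------------------
# Welch t test
# ---------------------------------------------------------------------------

def welch_t(
    x: Sequence[float], y: Sequence[float], tail: Tail = "two_sided"
) -> TestResult:
    """Welch unequal-variance t test with Satterthwaite degrees of freedom."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise DegenerateDataError("each group needs at least 2 values")
    vx = float(xa.var(ddof=1))
    vy = float(ya.var(ddof=1))
    if vx == 0.0 and vy == 0.0:
        if float(xa.mean()) == float(ya.mean()):
            raise DegenerateDataError(
                "zero variance in both groups with equal means: t undefined"
            )
        # infinite separation: report the limiting p-value
        t_stat = math.inf if xa.mean() > ya.mean() else -math.inf
        df = float(xa.size + ya.size - 2)
    else:
        sx2, sy2 = vx / xa.size, vy / ya.size
        t_stat = float((xa.mean() - ya.mean()) / math.sqrt(sx2 + sy2))
        df = (sx2 + sy2) ** 2 / (
            (sx2**2 / (xa.size - 1)) + (sy2**2 / (ya.size - 1))
        )
    if tail == "one_sided_greater":
        p = float(_t_dist.sf(t_stat, df))
    elif tail == "one_sided_less":
        p = float(_t_dist.cdf(t_stat, df))
    else:
        p = float(2 * _t_dist.sf(abs(t_stat), df))
    return TestResult(statistic=t_stat, p=p, tail=tail)


# ---------------------------------------------------------------------------
# Mantel-Cox log-rank test
# ---------------------------------------------------------------------------

def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Sequence,
) -> TestResult:
    """Two-group Mantel-Cox log-rank test.

    Chi-square statistic (O - E)^2 / V for the first group, with the
    hypergeometric variance summed over distinct event times; ties are
    handled by simultaneous risk-set accounting.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be coded 0/1")
    labels = np.unique(g)
    if len(labels) != 2:
        raise DegenerateDataError(f"need exactly 2 groups, got {len(labels)}")
    in_a = g == labels[0]
    if in_a.all() or (~in_a).all():
        raise DegenerateDataError("a group is empty")

    observed = expected = variance = 0.0
    for tau in np.unique(t[e == 1]):
        at_risk = t >= tau
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d_tot = int(((t == tau) & (e == 1)).sum())
        d_a = int(((t == tau) & (e == 1) & in_a).sum())
        if n_tot == 0:
            continue
        observed += d_a
        expected += d_tot * n_a / n_tot
        if n_tot > 1:
            variance += (
                d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if variance == 0.0:
        return TestResult(statistic=0.0, p=1.0, tail="two_sided")
    stat = (observed - expected) ** 2 / variance
    p = float(_chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), p=p, tail="two_sided")


# ---------------------------------------------------------------------------
# ROC AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney estimator.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    if not set(np.unique(lab)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = s[lab == 1]
    neg = s[lab == 0]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateDataError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """ROC curve points (FPR, TPR) at every distinct score threshold."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1], [-np.inf]])
    n_pos = max(int((lab == 1).sum()), 1)
    n_neg = max(int((lab == 0).sum()), 1)
    pts = []
    for thr in thresholds:
        pred = s >= thr
        tpr = float((pred & (lab == 1)).sum() / n_pos)
        fpr = float((pred & (lab == 0)).sum() / n_neg)
        pts.append((fpr, tpr))
    return np.asarray(pts)
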