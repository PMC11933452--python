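"""Statistical primitives with exact small-sample behavior.

The analyses downstream lean on a small set of classical tests: Pearson
correlation with a Fisher-z confidence interval, Bonferroni-controlled
correlation matrices, Kruskal-Wallis, Wilcoxon rank-sum (Mann-Whitney U),
the Wilcoxon signed-rank test, Cohen's d and one-sample t-tests.

Two of these are computed by full enumeration at small n, because the
cohort contrasts they serve compare vectors of only five paired values,
where asymptotic p-values are meaningless:

* ``rank_sum`` enumerates all assignments of pooled mid-ranks to the two
  groups when ``n_a + n_b <= exact_threshold`` (ties allowed), and falls
  back to the normal approximation with tie and continuity correction
  otherwise.
* ``signed_rank`` enumerates all ``2**n`` sign patterns for ``n <= 12``
  and uses the normal approximation beyond.

The Fisher-z interval uses ``tanh(atanh(r) +- z_crit / sqrt(n - 3))``;
this is the convention under which published intervals such as
[-0.356, -0.040] for r = -0.203 at n = 142 reproduce to the printed
precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TwoSampleResult",
    "SignedRankResult",
    "pearson_ci",
    "correlation_matrix",
    "kruskal_wallis",
    "rank_sum",
    "signed_rank",
    "cohens_d",
    "one_sample_t",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with Fisher-z confidence interval."""

    r: float
    n: int
    p: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    ci_defined: bool = False
    alpha: float = 0.05

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass(frozen=True)
class TwoSampleResult:
    """Two-sample test outcome with effect size.

    ``d`` follows the group1 - group2 sign convention. ``method`` records
    whether the p-value came from exact enumeration or an approximation.
    """

    statistic: float
    p: float
    d: float
    n1: int
    n2: int
    method: str
    alternative: str = "two-sided"


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p: float
    n: int  # pairs retained after dropping zero differences
    n_zero: int
    method: str
    alternative: str = "two-sided"
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Pearson correlation and Fisher-z interval

def pearson_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with two-sided p and Fisher-z CI.

    The CI is ``tanh(atanh(r) +- z_{1-alpha/2}/sqrt(n-3))``. It is only
    reported for ``n >= 4`` and ``|r| < 1``; otherwise the result carries
    ``ci_defined=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 for a correlation, got n={n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input to pearson_ci")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if n >= 4 and abs(r) < 1.0 - 1e-12:
        zcrit = float(sps.norm.ppf(1 - alpha / 2))
        z = math.atanh(r)
        half = zcrit / math.sqrt(n - 3)
        return CorrelationResult(
            r=r, n=n, p=float(p),
            ci_low=math.tanh(z - half), ci_high=math.tanh(z + half),
            ci_defined=True, alpha=alpha,
        )
    return CorrelationResult(r=r, n=n, p=float(p), alpha=alpha)


@dataclass(frozen=True)
class CorrelationMatrixResult:
    """All pairwise correlations of a table's columns plus the Bonferroni
    threshold ``alpha / n_pairs`` against which raw p-values are judged."""

    columns: tuple[str, ...]
    matrix: pd.DataFrame  # symmetric, unit diagonal
    pairs: dict[tuple[str, str], CorrelationResult]
    alpha: float
    threshold: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def significant(self) -> list[tuple[str, str]]:
        return [k for k, v in self.pairs.items() if v.p < self.threshold]


def correlation_matrix(
    table: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> CorrelationMatrixResult:
    """Pairwise Pearson correlations over the columns of ``table``."""
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns")
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pairs: dict[tuple[str, str], CorrelationResult] = {}
    for a, b in itertools.combinations(cols, 2):
        res = pearson_ci(table[a].to_numpy(), table[b].to_numpy(), alpha=alpha)
        pairs[(a, b)] = res
        mat.loc[a, b] = mat.loc[b, a] = res.r
    threshold = alpha / len(pairs)
    return CorrelationMatrixResult(
        columns=tuple(cols), matrix=mat, pairs=pairs,
        alpha=alpha, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# rank-based tests

def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df.

    Identical pooled values (zero spread anywhere) yield H = 0, p = 1
    rather than an error: that is the H the rank formula gives in the
    limit, and constant rating columns are a legitimate degenerate input.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _u_statistic(ranks_a_sum: float, n_a: int) -> float:
    return ranks_a_sum - n_a * (n_a + 1) / 2.0


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact Mann-Whitney p by enumerating all group assignments.

    Mid-ranks make the enumeration valid under ties; the two-sided
    p-value is the probability of a U at least as far from its null mean
    as observed.
    """
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_obs = _u_statistic(float(ranks[:n_a].sum()), n_a)
    mu = n_a * n_b / 2.0
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n_a + n_b), n_a)),
        dtype=np.intp,
    ).reshape(-1, n_a)
    u_all = ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2.0
    eps = 1e-9
    if alternative == "two-sided":
        p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - eps))
    elif alternative == "greater":
        p = float(np.mean(u_all >= u_obs - eps))
    elif alternative == "less":
        p = float(np.mean(u_all <= u_obs + eps))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return u_obs, p


def rank_sum(
    a,
    b,
    alternative: str = "two-sided",
    exact_threshold: int = 20,
) -> TwoSampleResult:
    """Wilcoxon rank-sum / Mann-Whitney U test.

    Exact enumeration of all ``C(n_a+n_b, n_a)`` assignments when the
    pooled size is at most ``exact_threshold`` (mid-ranks handle ties);
    otherwise the normal approximation with tie and continuity
    correction via scipy. The reported statistic is U for group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    try:
        d = cohens_d(a, b)
    except ValueError:
        d = math.nan
    if a.size + b.size <= exact_threshold:
        u, p = _exact_rank_sum_p(a, b, alternative)
        return TwoSampleResult(u, p, d, a.size, b.size, "exact-enumeration", alternative)
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic",
                           use_continuity=True)
    return TwoSampleResult(float(res.statistic), float(res.pvalue), d,
                           a.size, b.size, "normal-approx", alternative)


def signed_rank(
    differences,
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> SignedRankResult:
    """Wilcoxon signed-rank test on a vector of paired differences.

    Zero differences are dropped (the convention is recorded in the
    result). For ``n <= exact_max_n`` the null is enumerated over all
    ``2**n`` sign patterns — at n = 5 the smallest attainable one-sided p
    is 1/32 and the smallest two-sided p is 2/32. Beyond that a normal
    approximation with tie correction is used.
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.ndim != 1 or diffs.size == 0:
        raise ValueError("differences must be a nonempty 1-D array")
    nonzero = diffs[diffs != 0]
    n_zero = diffs.size - nonzero.size
    if nonzero.size == 0:
        return SignedRankResult(0.0, 1.0, 0, n_zero, "degenerate",
                                alternative, degenerate=True)
    ranks = _midranks(np.abs(nonzero))
    w_pos = float(ranks[nonzero > 0].sum())
    n = nonzero.size
    mu = n * (n + 1) / 4.0
    eps = 1e-9
    if n <= exact_max_n:
        signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1  # 1 = positive
        w_all = signs @ ranks
        if alternative == "two-sided":
            p = float(np.mean(np.abs(w_all - mu) >= abs(w_pos - mu) - eps))
        elif alternative == "greater":
            p = float(np.mean(w_all >= w_pos - eps))
        elif alternative == "less":
            p = float(np.mean(w_all <= w_pos + eps))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return SignedRankResult(w_pos, p, n, n_zero, "exact-enumeration", alternative)
    # normal approximation with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_pos - mu) / sigma
    if alternative == "two-sided":
        p = 2 * float(sps.norm.sf(abs(z)))
    elif alternative == "greater":
        p = float(sps.norm.sf(z))
    else:
        p = float(sps.norm.cdf(z))
    return SignedRankResult(w_pos, min(p, 1.0), n, n_zero, "normal-approx", alternative)


# ---------------------------------------------------------------------------
# parametric pieces

def cohens_d(a, b) -> float:
    """Cohen's d with pooled SD; sign convention mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group for Cohen's d")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / math.sqrt(pooled))


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of ``values`` against ``mu0``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need n >= 2 for a t-test")
    if np.ptp(values) == 0:
        raise ValueError("zero variance in one_sample_t input")
    t, p = sps.ttest_1samp(values, mu0)
    return float(t), float(p)
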