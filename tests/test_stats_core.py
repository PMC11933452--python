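"""Statistical primitives: exact small-sample behavior and conventions."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import infotrans as it
from infotrans.stats_core import correlation_matrix
import pandas as pd


class TestPearsonCI:
    @pytest.mark.parametrize("target_r,n,lo,hi", [
        (-0.203, 142, -0.356, -0.040),
        (0.536, 142, 0.407, 0.644),
    ])
    def test_fisher_z_interval_matches_published_convention(self, target_r, n, lo, hi):
        """The Fisher-z CI with 1.96/sqrt(n-3) reproduces printed intervals."""
        z = math.atanh(target_r)
        half = sps.norm.ppf(0.975) / math.sqrt(n - 3)
        assert math.tanh(z - half) == pytest.approx(lo, abs=1e-3)
        assert math.tanh(z + half) == pytest.approx(hi, abs=1e-3)
        # and the implementation agrees on data constructed to give that r
        rng = np.random.default_rng(7)
        x = rng.standard_normal(n)
        xc = (x - x.mean()) / x.std()
        e = rng.standard_normal(n)
        ec = e - e.mean()
        ec -= (ec @ xc) / (xc @ xc) * xc  # orthogonal to centered x
        ec /= ec.std()
        y = target_r * xc + math.sqrt(1 - target_r ** 2) * ec
        res = it.pearson_ci(x, y)
        assert res.r == pytest.approx(target_r, abs=1e-9)
        assert res.ci_low == pytest.approx(lo, abs=1e-3)
        assert res.ci_high == pytest.approx(hi, abs=1e-3)

    def test_perfect_correlation_flagged(self):
        x = np.arange(10.0)
        res = it.pearson_ci(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert not res.ci_defined

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            it.pearson_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_small_n_has_no_ci(self):
        res = it.pearson_ci([1, 2, 5], [2, 1, 4])
        assert not res.ci_defined


class TestCorrelationMatrix:
    def test_bonferroni_thresholds(self):
        rng = np.random.default_rng(0)
        df5 = pd.DataFrame(rng.standard_normal((30, 5)), columns=list("abcde"))
        res = correlation_matrix(df5, alpha=0.05)
        assert res.n_pairs == 10
        assert res.threshold == pytest.approx(0.005)

        df2 = df5[["a", "b"]]
        assert correlation_matrix(df2, alpha=0.05).threshold == pytest.approx(0.05)

        df10 = pd.DataFrame(rng.standard_normal((30, 10)))
        assert correlation_matrix(df10).n_pairs == 45

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((20, 4)))
        mat = correlation_matrix(df).matrix.to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = it.kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert h == 0.0 and p == 1.0

    def test_matches_hand_rank_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        # no ties: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2
        ranks = {v: i + 1 for i, v in enumerate(sorted(sum(groups, [])))}
        n = 6
        h_hand = 12 / (n * (n + 1)) * sum(
            len(g) * (np.mean([ranks[v] for v in g]) - (n + 1) / 2) ** 2
            for g in groups)
        h, p = it.kruskal_wallis(groups)
        assert h == pytest.approx(h_hand, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(h_hand, df=2), rel=1e-12)

    def test_five_groups_use_four_df(self):
        rng = np.random.default_rng(2)
        groups = [rng.standard_normal(10) for _ in range(5)]
        h, p = it.kruskal_wallis(groups)
        assert p == pytest.approx(sps.chi2.sf(h, df=4), rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            it.kruskal_wallis([[1, 2], []])


def permutation_rank_sum_oracle(a, b, alternative):
    """Brute-force oracle: rank-sum p over all permutations of pooled values."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    mu = n_a * len(b) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    eps = 1e-9
    if alternative == "two-sided":
        hits = [abs(u - mu) >= abs(u_obs - mu) - eps for u in us]
    elif alternative == "greater":
        hits = [u >= u_obs - eps for u in us]
    else:
        hits = [u <= u_obs + eps for u in us]
    return float(np.mean(hits))


class TestRankSum:
    def test_separated_groups_exact_p(self):
        res = it.rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact-enumeration"
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        res = it.rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_swap_flips_d_not_p(self):
        a, b = [1.0, 3.0, 2.0, 5.0], [4.0, 6.0, 7.0]
        r1, r2 = it.rank_sum(a, b), it.rank_sum(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r1.d == pytest.approx(-r2.d)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_oracle_equivalence_small_samples(self, alternative):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n_a = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 5))
            # mix of tied and untied inputs
            a = rng.integers(0, 6, size=n_a).astype(float)
            b = rng.integers(0, 6, size=n_b).astype(float)
            res = it.rank_sum(a, b, alternative=alternative)
            assert res.p == pytest.approx(
                permutation_rank_sum_oracle(a, b, alternative), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.standard_normal(5)
            b = rng.standard_normal(6)
            res = it.rank_sum(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_p_monotone_in_u_distance(self):
        # fixed n: sweep the observed configuration from balanced to extreme
        base = list(range(1, 9))
        ps = []
        us = []
        for pick in [(0, 2, 4, 6), (0, 1, 4, 5), (0, 1, 2, 4), (0, 1, 2, 3)]:
            a = [base[i] for i in pick]
            b = [base[i] for i in range(8) if i not in pick]
            res = it.rank_sum(a, b)
            ps.append(res.p)
            us.append(abs(res.statistic - 8))
        order = np.argsort(us)
        assert np.all(np.diff(np.array(ps)[order]) <= 1e-12)

    def test_large_sample_path(self):
        rng = np.random.default_rng(7)
        res = it.rank_sum(rng.standard_normal(30), rng.standard_normal(30) + 1)
        assert res.method == "normal-approx"
        assert res.p < 0.01


def sign_enumeration_oracle(diffs, alternative):
    """Brute-force oracle over all sign patterns (independent coding)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = len(d) * (len(d) + 1) / 4
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    eps = 1e-9
    if alternative == "two-sided":
        return float(np.mean([abs(w - mu) >= abs(w_obs - mu) - eps for w in ws]))
    if alternative == "greater":
        return float(np.mean([w >= w_obs - eps for w in ws]))
    return float(np.mean([w <= w_obs + eps for w in ws]))


class TestSignedRank:
    def test_all_negative_n5_extreme(self):
        diffs = [-0.5, -1.0, -0.2, -2.0, -0.1]
        less = it.signed_rank(diffs, alternative="less")
        assert less.statistic == 0.0
        assert less.p == pytest.approx(1 / 32)
        two = it.signed_rank(diffs)
        assert two.p == pytest.approx(2 / 32)

    def test_sign_flip_leaves_two_sided_p(self):
        diffs = np.array([0.3, -1.2, 0.8, 2.0, -0.4])
        assert it.signed_rank(diffs).p == pytest.approx(it.signed_rank(-diffs).p)

    def test_zero_differences_dropped(self):
        res = it.signed_rank([0.0, 0.0, 1.0, -2.0, 3.0])
        assert res.n == 3 and res.n_zero == 2

    def test_all_zero_degenerate(self):
        res = it.signed_rank([0.0, 0.0])
        assert res.degenerate and res.p == 1.0

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_oracle_equivalence_small_samples(self, alternative):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(1, 9))
            diffs = rng.integers(-4, 5, size=n).astype(float)
            if np.all(diffs == 0):
                continue
            res = it.signed_rank(diffs, alternative=alternative)
            assert res.p == pytest.approx(
                sign_enumeration_oracle(diffs, alternative), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(15):
            diffs = rng.standard_normal(8)
            res = it.signed_rank(diffs)
            ref = sps.wilcoxon(diffs, mode="exact")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(10)
        res = it.signed_rank(rng.standard_normal(30) + 1.0)
        assert res.method == "normal-approx"
        assert res.p < 0.01


class TestCohensD:
    def test_identical_groups_zero(self):
        assert it.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_example(self):
        assert it.cohens_d([2, 4], [1, 3]) == pytest.approx(1 / math.sqrt(2))

    def test_sign_convention(self):
        assert it.cohens_d([0.0, 0.1], [1.0, 1.1]) < 0

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            it.cohens_d([1, 1], [2, 2])


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        t, p = it.one_sample_t([-1.0, 1.0, -2.0, 2.0], 0.0)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_example(self):
        t, _ = it.one_sample_t([1, 2, 3], 0.0)
        assert t == pytest.approx(2 / (1 / math.sqrt(3)), rel=1e-12)

    def test_df_matches_n_minus_one(self):
        vals = [0.9, 0.95, 0.85, 0.8, 0.7, 0.99]  # six pairwise correlations
        t, p = it.one_sample_t(vals, 0.0)
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=5), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            it.one_sample_t([3, 3, 3], 0.0)


class TestTypeICalibration:
    """Under the null, each test rejects at ~5% (binomial 99% band)."""

    N_SIMS = 1000
    BAND = (0.0322, 0.0678)  # 99% binomial band around 0.05 at n=1000

    def _band_check(self, rejections):
        rate = rejections / self.N_SIMS
        lo, hi = self.BAND
        assert lo <= rate <= hi, f"rejection rate {rate} outside {self.BAND}"

    def test_rank_sum(self):
        rng = np.random.default_rng(100)
        rej = sum(it.rank_sum(rng.standard_normal(30),
                              rng.standard_normal(30)).p < 0.05
                  for _ in range(self.N_SIMS))
        self._band_check(rej)

    def test_signed_rank(self):
        rng = np.random.default_rng(101)
        rej = sum(it.signed_rank(rng.standard_normal(30)).p < 0.05
                  for _ in range(self.N_SIMS))
        self._band_check(rej)

    def test_one_sample_t(self):
        rng = np.random.default_rng(102)
        rej = sum(it.one_sample_t(rng.standard_normal(30), 0.0)[1] < 0.05
                  for _ in range(self.N_SIMS))
        self._band_check(rej)

    def test_pearson(self):
        rng = np.random.default_rng(103)
        rej = sum(it.pearson_ci(rng.standard_normal(30),
                                rng.standard_normal(30)).p < 0.05
                  for _ in range(self.N_SIMS))
        self._band_check(rej)
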