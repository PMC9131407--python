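import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vptlab.inference import (TestResult, jeffreys_bf_correlation, jzs_bf_ttest,
                              min_detectable_d, min_detectable_r, one_sample_t,
                              paired_t, pearson_r, rm_anova, t_test_power)


class TestOneSampleT:
    def test_worked_example(self):
        res = one_sample_t([1, 2, 3, 4, 5])
        assert res.statistic == pytest.approx(4.2426, abs=1e-4)
        assert res.df == 4
        assert res.effect_size == pytest.approx(1.897, abs=1e-3)

    def test_symmetric_values_give_t_zero(self):
        res = one_sample_t([-2, -1, 0, 1, 2], mu0=0)
        assert res.statistic == pytest.approx(0)
        assert res.p == pytest.approx(1)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([3.0, 3.0, 3.0])

    def test_paired_variant_on_identical_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_p_uniform_under_null(self, rng):
        """Null p-values are uniform (KS at alpha = .01, 500 replicates)."""
        ps = [one_sample_t(rng.normal(size=20)).p for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRmAnova:
    @staticmethod
    def _long(values):
        n, k = values.shape
        return pd.DataFrame({
            "pid": np.repeat(np.arange(n), k),
            "cond": np.tile([f"c{j}" for j in range(k)], n),
            "y": values.ravel(),
        })

    def test_two_level_factor_equals_squared_paired_t(self, rng):
        values = rng.normal(size=(15, 2))
        res = rm_anova(self._long(values), dv="y", within="cond", subject="pid")[0]
        t = paired_t(values[:, 0], values[:, 1])
        assert res.statistic == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert res.p == pytest.approx(t.p, rel=1e-10)

    def test_constant_shift_leaves_f_unchanged(self, rng):
        values = rng.normal(size=(12, 3))
        base = rm_anova(self._long(values), dv="y", within="cond", subject="pid")[0]
        shifted = rm_anova(self._long(values + 100.0), dv="y", within="cond",
                           subject="pid")[0]
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-8)

    def test_partial_eta_squared_from_f(self, rng):
        values = rng.normal(size=(12, 3))
        res = rm_anova(self._long(values), dv="y", within="cond", subject="pid")[0]
        df1, df2 = res.df
        assert res.effect_size == pytest.approx(
            res.statistic * df1 / (res.statistic * df1 + df2))
        assert 0 <= res.effect_size <= 1

    def test_gg_epsilon_attached_for_three_levels(self, rng):
        values = rng.normal(size=(12, 3))
        res = rm_anova(self._long(values), dv="y", within="cond", subject="pid")[0]
        assert "gg_epsilon" in res.extra and 1 / 2 <= res.extra["gg_epsilon"] <= 1

    def test_missing_cells_rejected(self, rng):
        df = self._long(rng.normal(size=(10, 2))).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova(df, dv="y", within="cond", subject="pid")


class TestJzsBf:
    def test_null_t_supports_null(self):
        assert jzs_bf_ttest(0.0, 61) < 1

    def test_monotone_in_t(self):
        bfs = [jzs_bf_ttest(t, 61) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_consistency_in_n(self):
        """For a fixed true standardized effect, evidence accumulates with n."""
        bfs = [jzs_bf_ttest(0.5 * math.sqrt(n), n) for n in (20, 50, 100, 200)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_reproduces_published_group_tests(self):
        """The JZS BF reproduces the printed values for the group regression
        t statistics at n = 61."""
        assert jzs_bf_ttest(7.209, 61) == pytest.approx(1.000e7, rel=0.02)
        assert jzs_bf_ttest(19.181, 61) == pytest.approx(1.189e24, rel=0.02)

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.0, 4.0, 8.0])
    @pytest.mark.parametrize("n", [10, 61])
    def test_quadrature_matches_monte_carlo_oracle(self, t, n):
        """Quadrature within 1% of brute-force Monte-Carlo integration over
        prior draws of g ~ InvGamma(1/2, r^2/2)."""
        rng = np.random.default_rng(1234)
        r2 = 0.5
        g = stats.invgamma.rvs(0.5, scale=r2 / 2, size=10 ** 6, random_state=rng)
        nu = n - 1
        lik = ((1 + n * g) ** -0.5
               * ((1 + t ** 2 / (nu * (1 + n * g))) / (1 + t ** 2 / nu)) ** (-(nu + 1) / 2))
        assert jzs_bf_ttest(t, n) == pytest.approx(lik.mean(), rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_ttest(float("nan"), 61)
        with pytest.raises(ValueError):
            jzs_bf_ttest(2.0, 1)

    def test_cross_check_against_pingouin(self):
        import pingouin as pg
        for t, n in ((2.0, 30), (5.0, 61)):
            assert jzs_bf_ttest(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n)), rel=1e-4)


class TestCorrelationBf:
    def test_null_r_supports_null_and_decreases_in_n(self):
        assert jeffreys_bf_correlation(0.0, 61) < 1
        assert jeffreys_bf_correlation(0.0, 200) < jeffreys_bf_correlation(0.0, 20)

    def test_symmetry(self):
        assert jeffreys_bf_correlation(0.38, 61) == pytest.approx(
            jeffreys_bf_correlation(-0.38, 61), rel=1e-8)

    @pytest.mark.parametrize("r", [0.0, 0.2, 0.38])
    @pytest.mark.parametrize("n", [20, 61])
    def test_quadrature_matches_monte_carlo_oracle(self, r, n):
        """Quadrature within 2% of Monte-Carlo prior draws (uniform rho)."""
        from vptlab.inference import _corr_likelihood
        rng = np.random.default_rng(99)
        rho = rng.uniform(-1, 1, size=400_000)
        mc = _corr_likelihood(r, rho, n).mean() / float(_corr_likelihood(r, np.array(0.0), n))
        assert jeffreys_bf_correlation(r, n) == pytest.approx(mc, rel=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jeffreys_bf_correlation(1.0, 61)
        with pytest.raises(ValueError):
            jeffreys_bf_correlation(0.3, 2)


class TestPearson:
    def test_perfect_linear_relation(self):
        res = pearson_r([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.statistic == pytest.approx(1.0)

    def test_three_point_worked_set(self):
        res = pearson_r([0, 1, 2], [0, 1, 4])
        assert res.statistic == pytest.approx(0.960769, abs=1e-5)
        assert res.df == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        for _ in range(500):
            res = pearson_r(rng.normal(size=25), rng.normal(size=25))
            rejections += res.p < 0.05
        rate = rejections / 500
        assert abs(rate - 0.05) < 1.96 * math.sqrt(0.05 * 0.95 / 500) + 0.01


class TestPower:
    def test_one_tailed_minimum_detectable_d(self):
        assert round(min_detectable_d(61, alpha=0.05, power=0.80, tails=1), 2) == 0.32

    def test_two_tailed_minimum_detectable_d(self):
        assert round(min_detectable_d(61, alpha=0.05, power=0.80, tails=2), 2) == 0.36

    def test_power_roundtrip(self):
        for tails in (1, 2):
            d = min_detectable_d(61, tails=tails)
            assert 0.80 <= t_test_power(d, 61, tails=tails) <= 0.80 + 1e-4

    def test_monotone_decreasing_in_n(self):
        ds = [min_detectable_d(n) for n in (20, 40, 80, 160)]
        assert all(d2 < d1 for d1, d2 in zip(ds, ds[1:]))
        rs = [min_detectable_r(n) for n in (20, 40, 80, 160)]
        assert all(r2 < r1 for r1, r2 in zip(rs, rs[1:]))

    def test_fisher_z_closed_form(self):
        assert min_detectable_r(61, tails=2) == pytest.approx(0.352, abs=5e-4)
        # z_power = 0 limit at power 0.5
        za = stats.norm.ppf(0.95)
        assert min_detectable_r(61, power=0.5, tails=1) == pytest.approx(
            math.tanh(za / math.sqrt(58)))

    def test_invalid_queries_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_d(61, alpha=0.0)
        with pytest.raises(ValueError):
            min_detectable_r(3)


def test_testresult_validates_p():
    with pytest.raises(ValueError):
        TestResult("bad", 1.0, 10, p=1.5, effect_size=0.1, effect_size_name="d")
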