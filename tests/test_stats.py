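"""Statistical battery: oracle equivalence, calibration, power, edges."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from rfacurve import DegenerateInputError
from rfacurve.stats import (
    bca_bootstrap_ci,
    flag_outliers,
    levene,
    marginal_means,
    one_way_anova,
    shapiro_wilk,
    spearman_correlation,
    tukey_hsd,
    two_way_anova,
)


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            shapiro_wilk(rng.normal(size=50)).p_value < 0.05 for _ in range(100)
        )
        assert rejections <= 10

    def test_exponential_samples_usually_rejected(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            shapiro_wilk(rng.exponential(size=50)).p_value < 0.05
            for _ in range(100)
        )
        assert rejections >= 90

    def test_preconditions(self):
        with pytest.raises(DegenerateInputError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            shapiro_wilk([3.0] * 10)


class TestLevene:
    def test_identical_groups(self):
        r = levene([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_unequal_spread_power(self):
        rng = np.random.default_rng(3)
        hits = sum(
            levene([rng.normal(0, 1, 30), rng.normal(0, 3, 30)]).p_value < 0.05
            for _ in range(100)
        )
        assert hits >= 90

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            levene([[1.0, 2, 3]])


class TestOneWayAnova:
    def test_matches_reference_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            sizes = rng.integers(3, 9, size=rng.integers(2, 5))
            groups = [rng.normal(rng.normal(), 1.0, n) for n in sizes]
            vals = np.concatenate(groups)
            labels = np.repeat([f"g{i}" for i in range(len(groups))], sizes)
            mine = one_way_anova(vals, labels)
            f_ref, p_ref = sps.f_oneway(*groups)
            assert mine.statistic == pytest.approx(f_ref, rel=1e-10)
            assert mine.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_separated_groups(self):
        vals = np.array([0.0, 0.01, -0.01, 1.0, 1.01, 0.99])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        assert one_way_anova(vals, labels).p_value < 1e-6

    def test_null_p_values_uniform(self):
        """Under H0 the p-value distribution is uniform (KS p > 0.01)."""
        rng = np.random.default_rng(5)
        labels = np.repeat(list("abcde"), 10)
        pvals = [
            one_way_anova(rng.normal(size=50), labels).p_value
            for _ in range(500)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestTwoWayAnova:
    @staticmethod
    def _sim(rng, cell_means, n=10):
        sol, temp, vals = [], [], []
        for (s, t), m in cell_means.items():
            sol += [s] * n
            temp += [t] * n
            vals.append(rng.normal(m, 1.0, n))
        return np.concatenate(vals), np.array(sol), np.array(temp)

    def test_matches_statsmodels_type1_on_balanced_data(self):
        rng = np.random.default_rng(6)
        cells = {(s, t): rng.normal() for s in "ab" for t in "xy"}
        vals, sol, temp = self._sim(rng, cells, n=6)
        mine = two_way_anova(vals, sol, temp)
        df = pd.DataFrame({"v": vals, "s": sol, "t": temp})
        ref = anova_lm(ols("v ~ C(s) * C(t)", data=df).fit(), typ=1)
        for key, row in (
            ("solution", "C(s)"),
            ("temperature", "C(t)"),
            ("interaction", "C(s):C(t)"),
        ):
            assert mine[key].statistic == pytest.approx(ref.loc[row, "F"], rel=1e-8)
            assert mine[key].p_value == pytest.approx(ref.loc[row, "PR(>F)"], rel=1e-8)
            assert mine[key].extra["ss"] == pytest.approx(
                ref.loc[row, "sum_sq"], rel=1e-8, abs=1e-10
            )

    def test_pure_interaction_power(self):
        """Cell means +d,-d,-d,+d with d = 1.5 sigma are detected in at
        least 80% of replicates at n=10 per cell."""
        rng = np.random.default_rng(7)
        d = 1.5
        hits = 0
        for _ in range(200):
            cells = {("a", "x"): d, ("a", "y"): -d, ("b", "x"): -d, ("b", "y"): d}
            vals, sol, temp = self._sim(rng, cells, n=10)
            hits += two_way_anova(vals, sol, temp)["interaction"].p_value < 0.05
        assert hits >= 160

    def test_null_uniform_all_effects(self):
        rng = np.random.default_rng(8)
        ps = {"solution": [], "temperature": [], "interaction": []}
        for _ in range(300):
            cells = {(s, t): 0.0 for s in "ab" for t in "xy"}
            vals, sol, temp = self._sim(rng, cells, n=5)
            res = two_way_anova(vals, sol, temp)
            for k in ps:
                ps[k].append(res[k].p_value)
        for k, pv in ps.items():
            assert sps.kstest(pv, "uniform").pvalue > 0.01

    def test_control_rows_excluded(self):
        rng = np.random.default_rng(9)
        cells = {(s, t): 0.0 for s in ("saline", "deionized")
                 for t in ("ambient", "refrigerated")}
        vals, sol, temp = self._sim(rng, cells, n=5)
        vals = np.concatenate([vals, rng.normal(100, 1, 5)])
        sol = np.concatenate([sol, ["none"] * 5])
        temp = np.concatenate([temp, ["none"] * 5])
        res = two_way_anova(vals, sol, temp)
        # the wildly different control cells must not influence the fit
        assert res["interaction"].extra["df_error"] == 16


class TestTukeyHsd:
    def test_identical_groups(self):
        df = tukey_hsd(np.tile([1.0, 2, 3, 4], 2), np.repeat(["a", "b"], 4))
        assert df.loc[0, "mean_diff"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc[0, "adjusted_p"] == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_p_dominates_pairwise_t(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        table = tukey_hsd(vals, labels)
        for _, row in table.iterrows():
            x = vals[labels == row.level_a]
            y = vals[labels == row.level_b]
            _, p_t = sps.ttest_ind(x, y)
            assert row.adjusted_p >= p_t - 1e-12

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=40)
        labels = np.repeat(["a", "b", "c", "d"], 10)
        mine = tukey_hsd(vals, labels).set_index(["level_a", "level_b"])
        ref = pairwise_tukeyhsd(vals, labels)
        for (g1, g2), p_adj, lo, hi in zip(
            itertools.combinations(ref.groupsunique, 2),
            ref.pvalues, ref.confint[:, 0], ref.confint[:, 1],
        ):
            row = mine.loc[(g1, g2)]
            assert row.adjusted_p == pytest.approx(p_adj, abs=1e-4)
            # statsmodels reports group2 - group1
            assert -row.mean_diff == pytest.approx((lo + hi) / 2, rel=1e-9)
            assert -row.ci_high == pytest.approx(lo, abs=1e-6)
            assert -row.ci_low == pytest.approx(hi, abs=1e-6)


class TestBcaBootstrap:
    def test_symmetric_data_close_to_percentile(self):
        rng = np.random.default_rng(12)
        data = rng.normal(5.0, 1.0, 100)
        bca = bca_bootstrap_ci(data, np.mean, B=2000, seed=1)
        boot = np.array(
            [data[rng.integers(0, 100, 100)].mean() for _ in range(2000)]
        )
        lo, hi = np.percentile(boot, [2.5, 97.5])
        sd = data.std(ddof=1)
        assert abs(bca.ci_low - lo) < 0.05 * sd
        assert abs(bca.ci_high - hi) < 0.05 * sd

    def test_deterministic_for_fixed_seed(self):
        data = np.random.default_rng(13).lognormal(size=40)
        a = bca_bootstrap_ci(data, np.mean, seed=99)
        b = bca_bootstrap_ci(data, np.mean, seed=99)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_matches_scipy_bca_on_skewed_data(self):
        data = np.random.default_rng(14).lognormal(size=80)
        mine = bca_bootstrap_ci(data, np.mean, B=4000, seed=5)
        ref = sps.bootstrap(
            (data,), np.mean, method="BCa", n_resamples=4000,
            random_state=np.random.default_rng(6), confidence_level=0.95,
        )
        tol = 0.06 * data.std(ddof=1)
        assert abs(mine.ci_low - ref.confidence_interval.low) < tol
        assert abs(mine.ci_high - ref.confidence_interval.high) < tol

    def test_degenerate_falls_back_to_percentile(self):
        ci = bca_bootstrap_ci([2.0] * 10, np.mean, B=500, seed=0)
        assert ci.degenerate and ci.method == "percentile"
        assert ci.ci_low == ci.ci_high == 2.0

    def test_preconditions(self):
        with pytest.raises(DegenerateInputError):
            bca_bootstrap_ci([1.0, 2.0, 3.0], np.mean)
        with pytest.raises(ValueError):
            bca_bootstrap_ci(np.arange(10.0), np.mean, B=50)


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert spearman_correlation([1, 2, 3, 4], [40, 30, 20, 10])[0] == -1.0

    def test_exact_p_close_to_t_approximation(self):
        """For n=8 the exact permutation p and the t approximation agree
        within 0.02 on moderately correlated data."""
        rng = np.random.default_rng(15)
        for _ in range(5):
            x = rng.normal(size=8)
            y = 0.5 * x + rng.normal(size=8)
            rho, p_exact = spearman_correlation(x, y)
            _, p_t = sps.spearmanr(x, y)
            assert abs(p_exact - p_t) < 0.02

    def test_exact_p_matches_brute_force(self):
        """Independent brute-force enumeration over all 6! pairings."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 6.0])
        rho, p = spearman_correlation(x, y)
        rx = sps.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(sps.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestFlagOutliers:
    def test_single_extreme(self):
        mask = flag_outliers([1.0, 2, 3, 4, 100])
        assert mask.tolist() == [False, False, False, False, True]

    def test_uniform_grid_clean(self):
        assert not flag_outliers(np.arange(1.0, 21.0)).any()

    def test_constant_values_clean(self):
        assert not flag_outliers([5.0] * 8).any()


class TestMarginalMeans:
    def test_single_level_mean(self):
        df = pd.DataFrame({"group": ["PURERF"] * 3, "value": [1.0, 2.0, 3.0]})
        mm = marginal_means(df)
        assert mm.loc[0, "mean"] == pytest.approx(2.0)
        assert mm.loc[0, "ci_low"] <= 2.0 <= mm.loc[0, "ci_high"]

    def test_parametric_and_bootstrap_widths_agree_large_n(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame({"group": ["DEI5"] * 100, "value": rng.normal(size=100)})
        par = marginal_means(df, ci_method="parametric")
        boo = marginal_means(df, ci_method="bca_bootstrap", seed=17)
        w_par = par.loc[0, "ci_high"] - par.loc[0, "ci_low"]
        w_boo = boo.loc[0, "ci_high"] - boo.loc[0, "ci_low"]
        assert abs(w_par - w_boo) / w_par < 0.10

    def test_control_reported_as_reference_level_in_factor_summary(self):
        df = pd.DataFrame(
            {
                "solution": ["none"] * 3 + ["saline"] * 3 + ["deionized"] * 3,
                "value": np.arange(9.0),
            }
        )
        mm = marginal_means(df, grouping="solution")
        assert set(mm["level"]) == {"PURERF", "saline", "deionized"}

    def test_small_level_rejected(self):
        df = pd.DataFrame({"group": ["DEI5", "DEI5", "PURERF"], "value": [1, 2, 3.0]})
        with pytest.raises(DegenerateInputError):
            marginal_means(df)
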