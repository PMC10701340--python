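"""Monte Carlo ANOVA, HPDI, allometric scaling, and Dixon's Q."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from whalemorph import inference as inf


def posterior_frame(means, variances, pops, whales=None):
    n = len(means)
    return pd.DataFrame(
        {
            "whale_id": whales or [f"w{i}" for i in range(n)],
            "population": pops,
            "posterior_mean": means,
            "posterior_variance": variances,
        }
    )


class TestHpdi:
    def test_uniform_spacing_width(self):
        x = np.arange(101) / 100
        lo, hi = inf.hpdi(x, 0.5)
        assert hi - lo == pytest.approx(0.50)
        assert lo == pytest.approx(0.0)  # earliest among tied windows

    def test_degenerate_identical_samples(self):
        assert inf.hpdi(np.full(50, 3.7), 0.95) == (3.7, 3.7)

    def test_normal_draws_match_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        lo, hi = inf.hpdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inf.hpdi(np.array([]), 0.5)

    @given(prob=st.floats(0.2, 0.95), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_width_monotone_in_prob_and_bounded(self, prob, seed):
        x = np.random.default_rng(seed).normal(size=500)
        lo1, hi1 = inf.hpdi(x, prob)
        lo2, hi2 = inf.hpdi(x, min(prob + 0.04, 0.99))
        assert hi2 - lo2 >= hi1 - lo1
        assert x.min() <= lo1 <= hi1 <= x.max()

    def test_matches_arviz(self):
        # independent reference implementation of the shortest interval
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, size=5000)
        ours = inf.hpdi(x, 0.9)
        ref = arviz.hdi(x, hdi_prob=0.9)
        assert ours[0] == pytest.approx(ref[0], abs=0.02)
        assert ours[1] == pytest.approx(ref[1], abs=0.02)


class TestMcAnova:
    def test_zero_variance_reduces_to_ols(self):
        df = posterior_frame([10, 10, 12, 12], [0.0] * 4, ["A", "A", "B", "B"])
        res = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=200, seed=0))
        assert res.coefficients == {"A": 10.0, "B": 12.0}
        row = res.contrasts.iloc[0]
        assert row["difference"] == pytest.approx(-2.0)
        assert (row["hpdi_low"], row["hpdi_high"]) == (-2.0, -2.0)
        assert row["significant"]

    def test_zero_variance_matches_statsmodels_on_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_pops = rng.integers(2, 4)
            pops, means = [], []
            for g in range(n_pops):
                n = int(rng.integers(2, 8))
                pops += [chr(65 + g)] * n
                means += list(rng.normal(20, 3, n))
            df = posterior_frame(means, [0.0] * len(means), pops)
            res = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=3, seed=1))
            # closed-form one-way OLS (cell-means) group coefficients
            X = pd.get_dummies(df["population"]).to_numpy(float)
            beta = np.linalg.lstsq(X, df["posterior_mean"], rcond=None)[0]
            for coef, ref in zip(res.coefficients.values(), beta):
                assert coef == pytest.approx(ref, abs=1e-10)

    def test_recovers_known_difference(self):
        rng = np.random.default_rng(7)
        means = np.concatenate([rng.normal(20, 0.3, 15), rng.normal(21.5, 0.3, 15)])
        df = posterior_frame(means, [0.09] * 30, ["A"] * 15 + ["B"] * 15)
        res = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=10_000, seed=2))
        obs_gap = means[15:].mean() - means[:15].mean()
        # MC average contrast equals the observed group-mean gap
        assert res.contrasts.iloc[0]["difference"] == pytest.approx(-obs_gap, abs=0.01)

    def test_replicate_count_consistency(self):
        rng = np.random.default_rng(9)
        df = posterior_frame(
            rng.normal(22, 1, 30), rng.uniform(0.01, 0.2, 30), ["A"] * 15 + ["B"] * 15
        )
        r1 = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=10_000, seed=3))
        r2 = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=100_000, seed=4))
        se = np.sqrt(df["posterior_variance"].mean() * (2 / 15) / 10_000)
        d1 = r1.contrasts.iloc[0]["difference"]
        d2 = r2.contrasts.iloc[0]["difference"]
        assert abs(d1 - d2) < 3 * se + 1e-3

    def test_significance_is_hpdi_excludes_zero(self):
        rng = np.random.default_rng(11)
        df = posterior_frame(
            rng.normal(22, 1, 24), rng.uniform(0.01, 1.0, 24),
            ["A"] * 8 + ["B"] * 8 + ["C"] * 8,
        )
        res = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=5000, seed=5))
        for row in res.contrasts.itertuples():
            assert row.significant == (not row.hpdi_low <= 0 <= row.hpdi_high)
            assert row.hpdi_low <= row.difference <= row.hpdi_high

    def test_degenerate_designs_rejected(self):
        with pytest.raises(inf.DegenerateDesign):
            inf.mc_anova(posterior_frame([1, 2], [0, 0], ["A", "A"]))
        with pytest.raises(inf.DegenerateDesign):
            inf.mc_anova(posterior_frame([1, 2, 3], [0, 0, 0], ["A", "A", "B"]))
        with pytest.raises(ValueError):
            inf.MCAnovaConfig(n_reps=0)

    def test_seeded_reproducibility(self):
        df = posterior_frame([10.0, 11, 12, 13], [0.5] * 4, ["A", "A", "B", "B"])
        a = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=2000, seed=6))
        b = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=2000, seed=6))
        pd.testing.assert_frame_equal(a.contrasts, b.contrasts)

    def test_negative_draw_counter_warns(self):
        df = posterior_frame([0.01, 0.01, 5, 5], [1.0] * 4, ["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="negative"):
            res = inf.mc_anova(df, config=inf.MCAnovaConfig(n_reps=2000, seed=8))
        assert res.negative_draws > 0

    def test_type_i_error_calibrated(self):
        """Equal-mean groups: HPDI excludes 0 in ~5% of outer replicates."""
        n_outer, n = 300, 15
        rng = np.random.default_rng(21)
        excl = np.zeros(3)
        for _ in range(n_outer):
            means = rng.normal(22.0, 0.3, 3 * n)  # truth equal; error sd 0.3
            df = posterior_frame(means, [0.09] * (3 * n),
                                 ["A"] * n + ["B"] * n + ["C"] * n)
            res = inf.mc_anova(
                df, config=inf.MCAnovaConfig(n_reps=2000, seed=int(rng.integers(2**31)))
            )
            excl += res.contrasts["significant"].to_numpy()
        for rate in excl / n_outer:
            assert 0.01 <= rate <= 0.09


class TestAllometry:
    def test_proportional_data_is_isometric(self):
        tl = np.array([18.0, 20, 22, 24, 26])
        fit = inf.allometry_fit(0.2 * tl, tl)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.classification == "isometry"

    def test_two_points_interpolated_exactly(self):
        fit = inf.allometry_fit([2.0, 3.0, 4.5], [20.0, 22.0, 24.0])
        resid = np.log([2.0, 3.0, 4.5]) - (fit.intercept + fit.slope * np.log([20.0, 22.0, 24.0]))
        # 3 points won't be exact, but the fit must match statsmodels
        ref = sm.OLS(np.log([2.0, 3.0, 4.5]), sm.add_constant(np.log([20.0, 22.0, 24.0]))).fit()
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-12)
        assert abs(resid.sum()) < 1e-12  # OLS residuals sum to zero

    def test_slope_ci_covers_generative_slope(self):
        rng = np.random.default_rng(13)
        covered = 0
        for _ in range(200):
            tl = rng.uniform(18, 26, 30)
            y = 0.01 * tl**1.3 * np.exp(rng.normal(0, 0.05, 30))
            fit = inf.allometry_fit(y, tl)
            covered += fit.slope_ci[0] <= 1.3 <= fit.slope_ci[1]
        assert covered / 200 >= 0.90

    def test_scale_free_slope(self):
        rng = np.random.default_rng(14)
        tl = rng.uniform(18, 26, 20)
        y = 0.2 * tl * np.exp(rng.normal(0, 0.03, 20))
        f1 = inf.allometry_fit(y, tl)
        f2 = inf.allometry_fit(3 * y, 3 * tl)
        assert f2.slope == pytest.approx(f1.slope, rel=1e-9)
        assert f2.intercept != pytest.approx(f1.intercept)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            inf.allometry_fit([1.0, -2.0, 3.0], [20.0, 21.0, 22.0])


class TestDixonQ:
    def test_formula_arithmetic(self):
        res = inf.dixon_q([1, 2, 3, 4, 10])
        assert res.q_high == pytest.approx(6 / 9)
        assert res.q_low == pytest.approx(1 / 9)

    def test_decision_against_published_critical_value(self):
        # r10 two-tailed critical value for n=5 at alpha=0.05 is 0.710
        res = inf.dixon_q([1, 2, 3, 4, 10], alpha=0.05)
        assert res.critical == 0.710
        assert not res.outlier_high  # 0.667 < 0.710: retain
        res2 = inf.dixon_q([1, 2, 3, 4, 14], alpha=0.05)
        assert res2.outlier_high  # 10/13 = 0.769 > 0.710: reject

    def test_all_equal_gives_no_test(self):
        res = inf.dixon_q([5.0] * 6)
        assert not res.tested and not res.any_outlier

    @pytest.mark.parametrize("n", [2, 31])
    def test_unsupported_n_rejected(self, n):
        with pytest.raises(ValueError):
            inf.dixon_q(np.arange(n))
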