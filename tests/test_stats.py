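import warnings

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from modgain.simulate import SimulationConfig, simulate_regression_cohort
from modgain.stats import (BootstrapSpec, bca_ci, bonferroni, fit_gain_model,
                           gain_anova, mixed_anova, partial_correlation)


def _single_group_cfg(seed, n=120, beta=1.8, inter=-2.4):
    return SimulationConfig(n_subjects=n, seed=seed,
                            groups={"walk": {"ef": 0.16, "crf": 0.55}},
                            beta_modularity=beta, beta_interaction=inter)


class TestMixedAnova:
    def test_null_interaction_near_zero(self, rng):
        n = 60
        pre = rng.normal(20, 4, n)
        post = pre + rng.normal(1, 1, n)
        group = np.repeat(["a", "b"], n // 2)
        res = mixed_anova(pre, post, group)
        assert res.loc["interaction", "p"] > 0.01
        assert set(res.index) >= {"group", "time", "interaction"}

    def test_time_f_equals_paired_t_squared(self, rng):
        """With 2 time points, the within-subject F is the paired t squared."""
        n = 40
        pre = rng.normal(10, 2, n)
        post = pre + rng.normal(0.5, 1, n)
        group = np.repeat(["a", "b"], n // 2)
        res = mixed_anova(pre, post, group)
        # oracle: paired t on the time effect, pooled within groups
        diffs = post - pre
        # classical decomposition: F_time tests the grand mean of the diffs
        ga = diffs[:n // 2]
        gb = diffs[n // 2:]
        mean_eff = (ga.mean() + gb.mean()) / 2
        se2 = (ga.var(ddof=1) + gb.var(ddof=1)) / 2 / (n // 2)
        t_equiv = mean_eff / np.sqrt(se2 / 2)
        assert res.loc["time", "F"] == pytest.approx(t_equiv**2, rel=1e-6)

    def test_planted_interaction_detected(self, rng):
        n = 120
        pre = rng.normal(20, 4, n)
        gain = np.where(np.arange(n) < n // 2, 2.0, 0.0)
        post = pre + gain + rng.normal(0, 1, n)
        group = np.repeat(["trained", "control"], n // 2)
        res = mixed_anova(pre, post, group)
        assert res.loc["interaction", "p"] < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            mixed_anova(np.arange(4.0), np.arange(4.0) + 1,
                        ["a", "a", "a", "b"])


class TestGainAnova:
    def test_four_group_fixture_with_null_group(self, rng):
        means = {"w": 0.5, "x": 0.5, "y": 0.4, "z": 0.0}
        gains, groups = [], []
        for name, mu in means.items():
            gains.append(rng.normal(mu, 0.3, 40))
            groups += [name] * 40
        res = gain_anova(np.concatenate(gains), groups)
        assert res["p"] < 1e-4
        assert res["per_group"]["z"]["p"] > 0.05
        assert res["per_group"]["w"]["p"] < 1e-6

    def test_orthogonal_covariate_leaves_f_close(self, rng):
        gains = np.concatenate([rng.normal(0.5, 0.3, 50), rng.normal(0.0, 0.3, 50)])
        groups = np.repeat(["a", "b"], 50)
        cov = rng.standard_normal(100)  # independent of group
        plain = gain_anova(gains, groups)
        adj = gain_anova(gains, groups, covariates=cov)
        assert adj["F"] == pytest.approx(plain["F"], rel=0.15)

    def test_matches_pingouin_anova(self, rng):
        gains = rng.normal(0, 1, 90)
        groups = np.repeat(["a", "b", "c"], 30)
        res = gain_anova(gains, groups)
        df = pd.DataFrame({"g": gains, "grp": groups})
        ref = pg.anova(data=df, dv="g", between="grp")
        assert res["F"] == pytest.approx(float(ref["F"][0]), rel=1e-8)
        assert res["p"] == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            gain_anova(np.array([0.0, 0.0, 1.0, 2.0]), ["a", "a", "b", "b"])


class TestFitGainModel:
    def test_noise_free_exact_recovery(self, rng):
        n = 50
        age = rng.uniform(60, 78, n)
        fd = rng.uniform(0.02, 0.2, n)
        ef = rng.standard_normal(n)
        q = rng.normal(0.3, 0.06, n)
        y = 0.1 - 0.01 * age + 0.5 * fd - 0.05 * ef + 1.8 * q - 2.4 * ef * q
        df = pd.DataFrame({"age": age, "mean_fd": fd, "ef_base": ef,
                           "modularity": q, "ef_gain": y})
        res = fit_gain_model(df, center=False, bootstrap_ci=False)
        b = res.table["B"]
        assert b["modularity"] == pytest.approx(1.8, abs=1e-8)
        assert b["ef_base_x_modularity"] == pytest.approx(-2.4, abs=1e-8)
        assert b["age"] == pytest.approx(-0.01, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_centering_changes_mains_not_fit(self, rng):
        cfg = _single_group_cfg(5, n=80)
        table, _ = simulate_regression_cohort(cfg)
        raw = fit_gain_model(table, center=False, bootstrap_ci=False)
        cen = fit_gain_model(table, center=True, bootstrap_ci=False)
        assert cen.r2 == pytest.approx(raw.r2, abs=1e-12)
        assert (cen.table.loc["ef_base_x_modularity", "B"]
                == pytest.approx(raw.table.loc["ef_base_x_modularity", "B"], rel=1e-9))

    def test_planted_sign_and_interaction_recovered(self):
        cfg = _single_group_cfg(101)
        table, _ = simulate_regression_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_gain_model(table, spec=BootstrapSpec(n_boot=1000, seed=0),
                                 center=False)
        assert res.table.loc["modularity", "B"] > 0
        assert res.table.loc["ef_base_x_modularity", "B"] < 0
        lo, hi = res.table.loc["modularity", ["ci_lo", "ci_hi"]]
        assert lo <= 1.8 <= hi

    def test_reduced_model(self):
        cfg = _single_group_cfg(7)
        table, _ = simulate_regression_cohort(cfg)
        res = fit_gain_model(table, reduced=True, bootstrap_ci=False)
        assert list(res.table.index) == ["intercept", "modularity"]
        assert res.df_model == 1

    def test_adjusted_r2_below_r2_and_residual_orthogonality(self):
        cfg = _single_group_cfg(13, n=60)
        table, _ = simulate_regression_cohort(cfg)
        res = fit_gain_model(table, bootstrap_ci=False)
        assert res.r2_adj <= res.r2
        x = np.column_stack([np.ones(res.n),
                             table["age"], table["mean_fd"],
                             table["ef_base"] - table["ef_base"].mean()])
        # residuals orthogonal to design columns
        assert np.all(np.abs(res.residuals @ x) < 1e-8 * res.n)

    def test_collinear_design_rejected(self, rng):
        n = 30
        q = rng.normal(0.3, 0.05, n)
        df = pd.DataFrame({"age": np.full(n, 65.0), "mean_fd": np.full(n, 0.1),
                           "ef_base": rng.standard_normal(n),
                           "modularity": q, "ef_gain": rng.standard_normal(n)})
        df["age"] = df["mean_fd"] * 100  # exact collinearity
        with pytest.raises(ValueError, match="ollinear"):
            fit_gain_model(df, bootstrap_ci=False)

    def test_too_small_sample_rejected(self):
        cfg = _single_group_cfg(3, n=6)
        table, _ = simulate_regression_cohort(cfg)
        with pytest.raises(ValueError, match="too small"):
            fit_gain_model(table, bootstrap_ci=False)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        res = partial_correlation(x, y)
        assert res["r"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert res["df"] == 38

    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(30)
        c = rng.standard_normal((30, 2))
        res = partial_correlation(x, x, covariates=c)
        assert res["r"] == pytest.approx(1.0, abs=1e-10)

    def test_matches_inverse_correlation_oracle(self, rng):
        """20-row fixture vs the inverse-correlation-matrix formula."""
        data = rng.standard_normal((20, 4))
        data[:, 1] += 0.6 * data[:, 0] + 0.3 * data[:, 2]
        x, y, cov = data[:, 0], data[:, 1], data[:, 2:]
        res = partial_correlation(x, y, covariates=cov)
        prec = np.linalg.inv(np.corrcoef(data, rowvar=False))
        expected = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert res["r"] == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        df = pd.DataFrame(rng.standard_normal((40, 3)), columns=["x", "y", "z"])
        res = partial_correlation(df["x"].to_numpy(), df["y"].to_numpy(),
                                  covariates=df["z"].to_numpy())
        ref = pg.partial_corr(data=df, x="x", y="y", covar="z")
        assert res["r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res["p"] == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_one_sided_halves_p(self, rng):
        x = rng.standard_normal(25)
        y = 0.4 * x + rng.standard_normal(25)
        two = partial_correlation(x, y, tail="two-sided")
        one = partial_correlation(x, y, tail="one-sided")
        assert one["p"] == pytest.approx(two["p"] / 2, rel=1e-9)


class TestBcaCi:
    def test_symmetric_mean_close_to_percentile(self, rng):
        data = rng.standard_normal(100)
        spec = BootstrapSpec(n_boot=4000, seed=0)
        ci = bca_ci(lambda d: d.mean(), data, spec,
                    vectorized_statistic=lambda d: d.mean(axis=1))
        assert abs(ci.z0) < 0.1 and abs(ci.accel) < 0.05
        boot = np.random.default_rng(0).integers(0, 100, (4000, 100))
        pct = np.quantile(data[boot].mean(axis=1), [0.025, 0.975])
        assert ci.lo == pytest.approx(pct[0], abs=0.08)
        assert ci.hi == pytest.approx(pct[1], abs=0.08)

    def test_monotone_transform_respected(self, rng):
        """log of a positive mean: transformed endpoints track the interval."""
        data = rng.lognormal(0, 0.3, 80)
        spec = BootstrapSpec(n_boot=3000, seed=42)
        ci_raw = bca_ci(lambda d: d.mean(), data, spec,
                        vectorized_statistic=lambda d: d.mean(axis=1))
        ci_log = bca_ci(lambda d: np.log(d.mean()), data, spec,
                        vectorized_statistic=lambda d: np.log(d.mean(axis=1)))
        assert np.log(ci_raw.lo) == pytest.approx(ci_log.lo, abs=0.02)
        assert np.log(ci_raw.hi) == pytest.approx(ci_log.hi, abs=0.02)

    def test_constant_statistic_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            bca_ci(lambda d: 1.0, rng.standard_normal(20),
                   BootstrapSpec(n_boot=1000, seed=0))

    def test_matches_scipy_bca(self, rng):
        """Independent cross-check against scipy's BCa implementation."""
        data = rng.standard_normal(60) ** 2
        spec = BootstrapSpec(n_boot=2000, seed=9)
        ours = bca_ci(lambda d: d.mean(), data, spec,
                      vectorized_statistic=lambda d: d.mean(axis=1))
        ref = sps.bootstrap((data,), np.mean, n_resamples=2000, method="BCa",
                            random_state=np.random.default_rng(9))
        assert ours.lo == pytest.approx(ref.confidence_interval.low, abs=0.05)
        assert ours.hi == pytest.approx(ref.confidence_interval.high, abs=0.05)


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert bonferroni(0.01, 6) == pytest.approx(0.06)
        assert bonferroni(0.5, 6) == 1.0
        assert bonferroni(0.2, 1) == pytest.approx(0.2)

    def test_m_must_cover_tests(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([0.01, 0.02, 0.03]), 2)
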