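"""Tests of the experiment statistics: proportions, LRT, trend test, fitness models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from wolbasim import (
    FitnessConfig,
    OutcomeCounts,
    fitness_compare,
    gen_fitness,
    logistic_trend,
    logit_prevalence_fit,
    lrt_heterogeneity,
    outcome_proportions,
)
from wolbasim.stats import _cox_stratified_breslow


def count_table(rows):
    return pd.DataFrame(rows, columns=["group", "replicate", "infected", "total"])


class TestOutcomeProportions:
    COUNTS = OutcomeCounts(visited=106, died=38, parasitoid_emerged=36,
                           whitefly_emerged=32, infected_of_emerged=30)

    def test_reported_percentages(self):
        props = outcome_proportions(self.COUNTS)
        assert props["died"].percent == 35.8
        assert props["parasitoid_emerged"].percent == 34.0
        assert props["whitefly_emerged"].percent == 30.2
        assert props["infected"].percent == 93.8

    def test_logit_interval_contains_estimate(self):
        props = outcome_proportions(self.COUNTS)
        for est in props.values():
            assert est.ci_low < est.proportion < est.ci_high

    def test_boundary_uses_exact_interval(self):
        oc = OutcomeCounts(visited=20, died=0, parasitoid_emerged=0,
                           whitefly_emerged=20, infected_of_emerged=0)
        est = outcome_proportions(oc)["infected"]
        assert est.boundary
        assert est.percent == 0.0
        assert est.ci_low == 0.0
        # Clopper-Pearson upper bound for 0/20
        assert est.ci_high == pytest.approx(1 - 0.025 ** (1 / 20), rel=1e-6)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            OutcomeCounts(visited=10, died=5, parasitoid_emerged=5,
                          whitefly_emerged=5, infected_of_emerged=0)
        with pytest.raises(ValueError):
            OutcomeCounts(visited=10, died=5, parasitoid_emerged=0,
                          whitefly_emerged=5, infected_of_emerged=6)


class TestLogitPrevalenceFit:
    def test_single_group_back_transforms_to_raw_proportion(self):
        table = count_table([(1, 1, 35, 40)])
        fit = logit_prevalence_fit(table)
        assert fit.loc[0, "estimate"] == pytest.approx(35 / 40, abs=1e-15)
        # interval from ln(35/5) +/- 1.96 sqrt(1/35 + 1/5)
        eta, se = np.log(35 / 5), np.sqrt(1 / 35 + 1 / 5)
        z = sps.norm.ppf(0.975)
        assert fit.loc[0, "ci_low"] == pytest.approx(
            1 / (1 + np.exp(-(eta - z * se))), rel=1e-12)
        assert fit.loc[0, "ci_high"] == pytest.approx(
            1 / (1 + np.exp(-(eta + z * se))), rel=1e-12)

    def test_replicates_pool_within_group(self):
        table = count_table([(1, 1, 10, 10), (1, 2, 8, 10)])
        fit = logit_prevalence_fit(table)
        assert fit.loc[0, "estimate"] == pytest.approx(0.9)

    def test_identical_groups_identical_estimates(self):
        table = count_table([(1, 1, 7, 10), (2, 1, 7, 10)])
        fit = logit_prevalence_fit(table)
        assert fit.loc[0, "estimate"] == fit.loc[1, "estimate"]

    def test_boundary_group_flagged(self):
        table = count_table([(1, 1, 10, 10)])
        assert bool(logit_prevalence_fit(table).loc[0, "boundary"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            logit_prevalence_fit(count_table([]))


class TestLRTHeterogeneity:
    def test_df_is_groups_minus_one(self):
        rng = np.random.default_rng(0)
        rows = [(g, r, int(rng.binomial(10, 0.875)), 10)
                for g in range(1, 6) for r in range(1, 5)]
        result = lrt_heterogeneity(count_table(rows))
        assert result.df == 4
        assert result.statistic_kind == "chi_square"

    def test_identical_groups_give_zero_statistic(self):
        rows = [(g, r, 9, 10) for g in range(1, 6) for r in range(1, 5)]
        result = lrt_heterogeneity(count_table(rows))
        assert result.statistic == pytest.approx(0.0, abs=1e-6)

    def test_two_group_statistic_matches_hand_arithmetic(self):
        # 8/10 vs 2/10: G = 2*(16 ln 1.6 + 4 ln 0.4) with pooled p = 0.5
        table = count_table([(1, 1, 8, 10), (2, 1, 2, 10)])
        result = lrt_heterogeneity(table)
        expected = 2 * (16 * np.log(1.6) + 4 * np.log(0.4))
        assert result.statistic == pytest.approx(expected, abs=1e-4)
        assert result.df == 1

    def test_statistic_is_nonnegative(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rows = [(g, r, int(rng.binomial(10, 0.8)), 10)
                    for g in range(1, 4) for r in range(1, 4)]
            assert lrt_heterogeneity(count_table(rows)).statistic >= 0.0

    def test_requires_two_groups_and_positive_totals(self):
        with pytest.raises(ValueError):
            lrt_heterogeneity(count_table([(1, 1, 5, 10)]))
        with pytest.raises(ValueError):
            lrt_heterogeneity(count_table([(1, 1, 5, 10), (2, 1, 0, 0)]))

    def test_detects_replicate_overdispersion_variance(self):
        # strong replicate effects within groups should yield sigma > 0 and
        # a smaller statistic than the fixed-effects G-test
        rows = []
        for g in range(1, 4):
            for r, k in zip(range(1, 5), (10, 9, 3, 2)):
                rows.append((g, r + 10 * g, k, 10))
        result = lrt_heterogeneity(count_table(rows))
        assert "random_intercept_variance_zero" not in result.flags


class TestLogisticTrend:
    def test_flat_proportions_give_zero_slope(self):
        table = count_table([(t, 1, 6, 10) for t in (24, 48, 72, 96)])
        result = logistic_trend(table)
        assert abs(result.statistic) < 1e-6

    def test_matches_direct_likelihood_maximization(self):
        table = count_table(
            [(24, 1, 9, 10), (48, 1, 7, 10), (72, 1, 4, 10), (96, 1, 2, 10)])
        result = logistic_trend(table)
        x = np.array([24.0, 48.0, 72.0, 96.0])
        y = np.array([9.0, 7.0, 4.0, 2.0])
        n = np.full(4, 10.0)

        def nll(theta):
            eta = theta[0] + theta[1] * x
            return -np.sum(y * eta - n * np.logaddexp(0.0, eta))

        opt = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options=dict(xatol=1e-12, fatol=1e-14, maxiter=20_000))
        assert result.estimate == pytest.approx(opt.x[1], abs=1e-6)
        assert result.estimate < 0
        # oracle SE from the observed information
        eta = opt.x[0] + opt.x[1] * x
        pi = 1 / (1 + np.exp(-eta))
        wgt = n * pi * (1 - pi)
        info = np.array([[wgt.sum(), (wgt * x).sum()],
                         [(wgt * x).sum(), (wgt * x * x).sum()]])
        se = np.sqrt(np.linalg.inv(info)[1, 1])
        assert result.se == pytest.approx(se, rel=1e-6)

    def test_saturated_counts_raise_separation_flag(self):
        table = count_table([(t, 1, 10, 10) for t in (24, 48, 72, 96)])
        assert "separation" in logistic_trend(table).flags

    def test_requires_two_distinct_times(self):
        with pytest.raises(ValueError):
            logistic_trend(count_table([(24, 1, 5, 10), (24, 2, 6, 10)]))


class TestFitnessCompare:
    def test_balanced_design_df_is_six(self):
        results = fitness_compare(gen_fitness(FitnessConfig(seed=0)))
        assert results["development_time"].df == 6
        assert results["fecundity"].df == 6

    def test_statistic_kinds_per_trait(self):
        results = fitness_compare(gen_fitness(FitnessConfig(seed=0)))
        kinds = {name: r.statistic_kind for name, r in results.items()}
        assert kinds == {
            "development_time": "t", "fecundity": "t",
            "immature_survival": "z", "longevity": "z", "sex_ratio": "z",
        }

    def test_identical_replicate_means_give_zero_t(self):
        ds = gen_fitness(FitnessConfig(seed=1))
        pairs = ds.pairs.copy()
        pairs["development_time"] = 18.0 + pairs["pair"] * 0.1
        ds.pairs = pairs
        result = fitness_compare(ds)["development_time"]
        assert result.statistic == 0.0

    def test_cox_matches_lifelines_stratified_fit(self):
        lifelines = pytest.importorskip("lifelines")
        ds = gen_fitness(FitnessConfig(seed=2))
        pairs = ds.pairs
        frame = pd.DataFrame({
            "T": pairs["longevity"], "E": 1,
            "arm": (pairs["arm"] == "infected").astype(float),
            "rep": pairs["replicate"],
        })
        cph = lifelines.CoxPHFitter()
        cph.fit(frame, duration_col="T", event_col="E", strata=["rep"])
        mine = _cox_stratified_breslow(
            pairs["longevity"].to_numpy(float),
            (pairs["arm"] == "infected").to_numpy(float),
            pairs["replicate"].to_numpy(),
        )
        assert mine.estimate == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        assert mine.se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-6)

    def test_longevity_benefit_detected_with_negative_log_hazard(self):
        # hazard ratio < 1 for infected means infected live longer
        results = fitness_compare(gen_fitness(FitnessConfig(seed=3)))
        assert results["longevity"].estimate < 0

    def test_single_replicate_arm_rejected(self):
        ds = gen_fitness(FitnessConfig(seed=4))
        keep = (ds.pairs["replicate"] == 1) | (ds.pairs["arm"] == "uninfected")
        with pytest.raises(ValueError):
            type(ds)(pairs=ds.pairs[keep], sex=None)

    def test_long_format_round_trip(self):
        ds = gen_fitness(FitnessConfig(seed=5))
        back = type(ds).from_long(ds.to_long())
        a = ds.pairs.sort_values(["arm", "replicate", "pair"]).reset_index(drop=True)
        b = back.pairs.sort_values(["arm", "replicate", "pair"]).reset_index(drop=True)
        for col in ("development_time", "fecundity", "longevity"):
            np.testing.assert_allclose(a[col], b[col])
        pd.testing.assert_frame_equal(
            ds.sex.sort_values(["arm", "replicate"]).reset_index(drop=True),
            back.sex.sort_values(["arm", "replicate"]).reset_index(drop=True)[
                ds.sex.columns],
        )


class TestEffectRecovery:
    def test_development_effect_sign_recovered(self):
        hits = 0
        for seed in range(60):
            results = fitness_compare(gen_fitness(FitnessConfig(seed=seed)))
            if results["development_time"].estimate < 0:
                hits += 1
        assert hits >= 57  # infected develop faster in >= 95% of datasets

    def test_null_hazard_ratio_centers_z_near_zero(self):
        zs = [
            fitness_compare(
                gen_fitness(FitnessConfig(seed=seed, longevity_hazard_ratio=1.0))
            )["longevity"].statistic
            for seed in range(40)
        ]
        assert abs(np.mean(zs)) < 2.5 / np.sqrt(40) * 2
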