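"""Cohort statistics: ascertainment, baseline table, association models."""

import numpy as np
import pandas as pd
import pytest

import aaci


def glucose_cohort(rows):
    return pd.DataFrame(rows, columns=["fasting_glucose", "two_hour_glucose"])


class TestAscertainment:
    @pytest.mark.parametrize(
        "fasting,two_hour,expected",
        [
            (7.0, 6.0, True),    # fasting threshold inclusive
            (5.1, 11.1, True),   # 2-h threshold inclusive
            (5.0, 7.0, False),
            (6.999, 11.099, False),
            (np.nan, 11.1, True),
            (np.nan, np.nan, None),  # indeterminate without any component
        ],
    )
    def test_threshold_rules(self, fasting, two_hour, expected):
        flag = aaci.ascertain_t2dm(glucose_cohort([(fasting, two_hour)]))
        if expected is None:
            assert pd.isna(flag.iloc[0])
        else:
            assert bool(flag.iloc[0]) is expected

    def test_self_report_and_treatment_qualify(self):
        cohort = pd.DataFrame(
            {"self_report_t2dm": [True, False], "t2dm_treatment": [False, True],
             "fasting_glucose": [5.0, 5.0], "two_hour_glucose": [5.0, 5.0]}
        )
        assert aaci.ascertain_t2dm(cohort).all()

    def test_monotone_in_glucose(self):
        # raising glucose never converts a case to a non-case
        rng = np.random.default_rng(0)
        fasting = rng.uniform(4, 9, 200)
        base = aaci.ascertain_t2dm(glucose_cohort(list(zip(fasting, [5.0] * 200))))
        raised = aaci.ascertain_t2dm(glucose_cohort(list(zip(fasting + 1.0, [5.0] * 200))))
        assert not (base.astype(bool) & ~raised.astype(bool)).any()


class TestBaselineTable:
    def test_shift_and_null_columns(self, sim_cohort):
        cohort, _, _ = sim_cohort
        rng = np.random.default_rng(1)
        cohort = cohort.copy()
        # injected mean shift along tertile; independent categorical stays flat
        shift = cohort["tertile"].map({"T1": 0.0, "T2": 2.0, "T3": 4.0})
        cohort["shifted"] = shift + rng.normal(0, 1, len(cohort))
        cohort["coin"] = rng.integers(0, 2, len(cohort))
        table = aaci.baseline_table(cohort, ["shifted", "age"], ["coin"])
        p = table.set_index("variable")["p_value"]
        assert p["shifted"] < 1e-3
        assert p["coin"] > 0.01

    def test_means_match_streaming_recomputation(self, sim_cohort):
        cohort, _, _ = sim_cohort
        table = aaci.baseline_table(cohort, ["bmi"], [])
        for t in ("T1", "T2", "T3"):
            x = cohort.loc[cohort["tertile"] == t, "bmi"]
            mean = float(table.loc[0, t].split(" ")[0])
            assert mean == pytest.approx(x.mean(), abs=5e-3)

    def test_empty_category_rejected(self, sim_cohort):
        cohort, _, _ = sim_cohort
        sub = cohort[cohort["tertile"] != "T2"]
        with pytest.raises(Exception):
            aaci.baseline_table(sub.assign(tertile=pd.Categorical(sub["tertile"],
                               categories=["T1", "T2", "T3"])), ["bmi"], [])


def _null_cohort(n=5000, seed=0, slope=0.0):
    rng = np.random.default_rng(seed)
    aaci_vals = rng.normal(3.4, 0.4, n)
    labels, _ = aaci.assign_tertiles(aaci_vals)
    score = pd.Series(labels).map({"T1": 0, "T2": 1, "T3": 2}).to_numpy()
    eta = -2.5 + slope * score
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {"aaci": aaci_vals, "tertile": labels, "t2dm_incident": y,
         "age": rng.normal(48, 10, n), "sex": rng.integers(0, 2, n)}
    )


LADDER = aaci.ModelLadder(models={"m1": ["age", "sex"]})


class TestTertileLogistic:
    def test_reference_category_is_exactly_one(self):
        res = aaci.fit_tertile_logistic(_null_cohort(), LADDER)["m1"]
        assert res.table.loc[0, "rr"] == 1.0
        assert res.table.loc[0, "category"] == "T1"

    def test_null_exposure_gives_flat_rrs(self):
        res = aaci.fit_tertile_logistic(_null_cohort(seed=5), LADDER)["m1"]
        rr = res.table["rr"].to_numpy()
        assert np.all(np.abs(np.log(rr[1:])) < 0.45)  # ~3 SEs at this n and incidence
        assert res.p_trend > 0.001

    def test_monotone_risk_recovered(self):
        # +0.4 log-odds per tertile step -> RR_T3 ~ exp(0.8)
        res = aaci.fit_tertile_logistic(_null_cohort(n=5000, seed=7, slope=0.4), LADDER)["m1"]
        assert res.table.loc[2, "rr"] == pytest.approx(np.exp(0.8), rel=0.35)
        assert res.p_trend < 0.05

    def test_trend_coefficient_approaches_injected_slope(self):
        cohort = _null_cohort(n=40000, seed=11, slope=0.4)
        import statsmodels.api as sm
        score = cohort["tertile"].map({"T1": 1, "T2": 2, "T3": 3}).astype(float)
        fit = sm.Logit(cohort["t2dm_incident"], sm.add_constant(score)).fit(disp=0)
        assert fit.params["tertile"] == pytest.approx(0.4, abs=0.06)

    def test_zero_case_category_non_estimable(self):
        cohort = _null_cohort(n=600, seed=1)
        cohort.loc[cohort["tertile"] == "T2", "t2dm_incident"] = 0
        res = aaci.fit_tertile_logistic(cohort, LADDER)["m1"]
        row = res.table.set_index("category").loc["T2"]
        assert np.isnan(row["rr"]) and row["cases"] == 0


class TestLinearStd:
    def test_outcome_equal_exposure_beta_one(self):
        cohort = _null_cohort(n=500, seed=2)
        cohort["y"] = cohort["aaci"]
        beta, p = aaci.fit_linear_std(cohort, "y", LADDER)["m1"]
        assert beta == pytest.approx(1.0, abs=1e-10)

    def test_null_outcome_beta_near_zero(self):
        rng = np.random.default_rng(1003)
        cohort = _null_cohort(n=10000, seed=3)
        cohort["y"] = rng.normal(size=len(cohort))
        beta, _ = aaci.fit_linear_std(cohort, "y", LADDER)["m1"]
        assert abs(beta) < 0.03

    def test_injected_standardized_slope_recovered(self):
        rng = np.random.default_rng(1004)
        cohort = _null_cohort(n=10000, seed=4)
        z = (cohort["aaci"] - cohort["aaci"].mean()) / cohort["aaci"].std(ddof=0)
        cohort["y"] = 0.1 * z + rng.normal(size=len(cohort))
        beta, p = aaci.fit_linear_std(cohort, "y", LADDER)["m1"]
        assert beta == pytest.approx(0.1, abs=0.02)  # within ~2 SEs
        assert p < 0.001

    def test_standardization_invariance_under_affine_rescaling(self):
        rng = np.random.default_rng(5)
        cohort = _null_cohort(n=2000, seed=5)
        cohort["y"] = 0.2 * cohort["aaci"] + rng.normal(size=len(cohort))
        b1, _ = aaci.fit_linear_std(cohort, "y", LADDER)["m1"]
        rescaled = cohort.assign(aaci=cohort["aaci"] * 7 - 3, y=cohort["y"] / 11 + 2)
        b2, _ = aaci.fit_linear_std(rescaled, "y", LADDER)["m1"]
        assert b1 == pytest.approx(b2, abs=1e-10)

    def test_zero_variance_rejected(self):
        cohort = _null_cohort(n=100, seed=6)
        cohort["y"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            aaci.fit_linear_std(cohort, "y", LADDER)


class TestSerumQuartiles:
    def make(self, n=6000, seed=8, slope=0.0):
        rng = np.random.default_rng(seed)
        cohort = _null_cohort(n=n, seed=seed)
        cohort["serum_valine"] = rng.normal(230, 40, n)
        q = cohort["serum_valine"].rank(pct=True)
        score = np.searchsorted([0.25, 0.5, 0.75], q)
        eta = -2.5 + slope * score
        cohort["t2dm_incident"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return cohort

    def test_reference_quartile_is_one(self):
        res = aaci.serum_quartile_logistic(self.make(), "valine", ["age", "sex", "aaci"])
        assert res.table.loc[0, "rr"] == 1.0 and res.table.loc[0, "category"] == "Q1"

    def test_protective_gradient_monotone(self):
        res = aaci.serum_quartile_logistic(self.make(slope=-0.3), "valine", ["age", "sex"])
        rr = res.table["rr"].to_numpy()
        assert rr[3] < rr[1] < 1.05 and rr[3] < 0.6

    def test_null_mediator_flat(self):
        res = aaci.serum_quartile_logistic(self.make(seed=9), "valine", ["age", "sex"])
        assert np.all(np.abs(np.log(res.table["rr"].to_numpy()[1:])) < 0.5)


class TestFoodGroupTrend:
    def test_intake_equal_exposure_perfect_rank_correlation(self):
        cohort = _null_cohort(n=300, seed=10)
        profile = pd.DataFrame({"rice": cohort["aaci"].to_numpy()}, index=cohort.index)
        out = aaci.food_group_trend(cohort, profile)
        assert out.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_permuted_intake_uncorrelated_and_constant_is_na(self):
        rng = np.random.default_rng(11)
        cohort = _null_cohort(n=4000, seed=11)
        profile = pd.DataFrame(
            {"perm": rng.permutation(cohort["aaci"].to_numpy()),
             "flat": np.ones(len(cohort))},
            index=cohort.index,
        )
        out = aaci.food_group_trend(cohort, profile).set_index("food_group")
        assert abs(out.loc["perm", "spearman_rho"]) < 0.04
        assert np.isnan(out.loc["flat", "spearman_rho"])

    def test_constructed_rising_group_significant(self):
        rng = np.random.default_rng(12)
        cohort = _null_cohort(n=4000, seed=12)
        profile = pd.DataFrame(
            {"rice": 100 + 30 * cohort["aaci"] + rng.normal(0, 20, len(cohort))},
            index=cohort.index,
        )
        out = aaci.food_group_trend(cohort, profile).set_index("food_group")
        assert out.loc["rice", "spearman_rho"] > 0.2
        assert out.loc["rice", "p_value"] < 1e-3
        assert out.loc["rice", "mean_T3"] > out.loc["rice", "mean_T1"]
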