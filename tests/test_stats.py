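"""Classical analyses: descriptives, t-tests, type-II ANOVA,
correlations, printed-summary group contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from toecurve import (
    analyze,
    correlations,
    describe,
    group_differences,
    two_group_test,
    two_way_anova,
)
from toecurve.reference import reference_group_means
from toecurve.stats import significance_mark


def balanced_frame(rng, n_per_cell=10, effect=0.0):
    rows = []
    for age in ("older", "younger"):
        for sex in ("male", "female"):
            shift = effect if sex == "male" else 0.0
            for v in rng.normal(shift, 1.0, n_per_cell):
                rows.append({"age_group": age, "sex": sex, "y": v})
    return pd.DataFrame(rows)


class TestDescribe:
    def test_mean_and_sample_sd(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "sex": ["male"] * 3,
                           "age_group": ["older"] * 3})
        out = describe(df, ["y"])
        all_row = out[(out.group == "all")].iloc[0]
        assert all_row["mean"] == 2.0
        assert all_row["sd"] == 1.0  # n-1 denominator

    def test_single_observation_flagged(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 5.0],
                           "sex": ["male", "female", "female"],
                           "age_group": ["older"] * 3})
        out = describe(df, ["y"])
        male = out[(out.grouping == "sex") & (out.group == "male")].iloc[0]
        assert np.isnan(male["sd"]) and male["flag"] == "single_observation"

    def test_group_sizes_sum_to_total(self, feature_frame):
        out = describe(feature_frame, ["peak_N"])
        sex_n = out[out.grouping == "sex"].set_index("group")["n"]
        assert sex_n["male"] == 9 and sex_n["female"] == 22
        assert sex_n.sum() == out[out.grouping == "all"]["n"].iloc[0] == 31


class TestTwoGroupTest:
    def test_identical_groups(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0] * 2,
                           "sex": ["male"] * 3 + ["female"] * 3})
        res = two_group_test(df, "y", "sex")
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_scipy_welch_and_student(self, feature_frame):
        from scipy import stats as sps
        male = feature_frame.query("sex=='male'")["peak_N"]
        female = feature_frame.query("sex=='female'")["peak_N"]
        res = two_group_test(feature_frame, "peak_N", "sex")
        ref = sps.ttest_ind(female, male, equal_var=False)
        assert res.t == pytest.approx(float(ref.statistic))
        assert res.p == pytest.approx(float(ref.pvalue))
        res_student = two_group_test(feature_frame, "peak_N", "sex",
                                     equal_var=True)
        assert res_student.df == len(feature_frame) - 2

    def test_small_group_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0],
                           "sex": ["male", "female", "female"]})
        with pytest.raises(ValueError):
            two_group_test(df, "y", "sex")

    def test_power_at_three_pooled_sds(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            df = pd.DataFrame({
                "y": np.concatenate([rng.normal(0, 1, 15), rng.normal(3, 1, 15)]),
                "sex": ["male"] * 15 + ["female"] * 15,
            })
            if two_group_test(df, "y", "sex").p < 0.001:
                hits += 1
        assert hits >= 99

    def test_shift_and_scale_equivariance(self, feature_frame):
        base = two_group_test(feature_frame, "peak_N", "sex")
        shifted = feature_frame.copy()
        shifted["peak_N"] = shifted["peak_N"] * 3.0 + 100.0
        res = two_group_test(shifted, "peak_N", "sex")
        assert res.p == pytest.approx(base.p)


class TestTwoWayAnova:
    def test_balanced_type2_equals_type1(self):
        df = balanced_frame(np.random.default_rng(3), effect=1.0)
        typ2 = two_way_anova(df, "y")
        model = smf.ols("y ~ C(age_group) * C(sex)", data=df).fit()
        typ1 = sm.stats.anova_lm(model, typ=1)
        for effect, raw in [("age_group", "C(age_group)"), ("sex", "C(sex)")]:
            assert typ2.loc[effect, "F"] == pytest.approx(typ1.loc[raw, "F"])

    def test_pure_sex_effect_detected(self):
        rng = np.random.default_rng(4)
        hits = sum(
            two_way_anova(balanced_frame(rng, effect=2.0), "y").loc["sex", "p"] < 0.05
            for _ in range(20)
        )
        assert hits >= 19

    def test_empty_cell_rejected(self):
        df = balanced_frame(np.random.default_rng(5))
        df = df[~((df.age_group == "older") & (df.sex == "male"))]
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(df, "y")

    def test_f_nonnegative_on_cohort(self, feature_frame):
        aov = two_way_anova(feature_frame, "peak_N")
        assert (aov["F"] >= 0).all()
        assert set(aov.index) == {"age_group", "sex", "age_group:sex"}


class TestCorrelations:
    def test_self_correlation_is_one_and_symmetric(self, feature_frame):
        mats, normality = correlations(feature_frame, ["peak_N", "grip_strength_N",
                                                       "bmi"])
        r = mats["all"].attrs["r"]
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert set(mats) == {"all", "older", "younger"}
        assert {"stratum", "variable", "non_normal"} <= set(normality.columns)

    def test_perfect_linear_pair(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                           "b": [2.0, 4.0, 6.0, 8.0],
                           "age_group": ["older"] * 4})
        mats, _ = correlations(df, ["a", "b"], by_group=None)
        assert mats["all"].attrs["r"].loc["a", "b"] == pytest.approx(1.0)

    def test_small_stratum_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0],
                           "age_group": ["older"] * 2})
        with pytest.raises(ValueError, match="n<3"):
            correlations(df, ["a", "b"], by_group=None)

    def test_induced_correlation_recovered(self):
        from toecurve import default_profiles, features_table, induce_correlation, simulate_cohort
        cohort = induce_correlation(
            simulate_cohort(default_profiles(n_scale=33), seed=9), 0.55, seed=10
        )
        table, _ = features_table(cohort.trials, cohort.subjects)
        mats, _ = correlations(table, ["peak_N", "grip_strength_N"], by_group=None)
        r = mats["all"].attrs["r"].loc["peak_N", "grip_strength_N"]
        assert 0.50 <= r <= 0.60  # Fisher-z interval around 0.55 at n~1000


class TestGroupDifferences:
    def test_reference_means_reproduce_reported_contrasts(self):
        diffs = group_differences(reference_group_means()).set_index("variable")
        assert diffs.loc["peak_N", "male_minus_female"] == pytest.approx(16.81)
        assert diffs.loc["rfd_N_per_s", "younger_minus_older"] == pytest.approx(15.16)
        assert diffs.loc["rise_time_s", "male_minus_female"] == pytest.approx(-1.80)
        assert diffs.loc["avg_after80_N", "male_minus_female"] == pytest.approx(10.81)

    def test_identical_means_give_zero(self):
        means = {"x": {"male": 5.0, "female": 5.0, "younger": 5.0, "older": 5.0}}
        diffs = group_differences(means)
        assert diffs.loc[0, "male_minus_female"] == 0.0
        assert diffs.loc[0, "younger_minus_older"] == 0.0

    def test_missing_stratum_rejected(self):
        with pytest.raises(ValueError, match="older"):
            group_differences({"x": {"male": 1.0, "female": 2.0, "younger": 3.0}})

    def test_accepts_describe_frame(self, feature_frame):
        diffs = group_differences(describe(feature_frame, ["peak_N"]))
        assert "male_minus_female" in diffs.columns and len(diffs) == 1


class TestReportAssembly:
    def test_analyze_bundles_everything(self, feature_frame):
        report = analyze(feature_frame)
        assert not report.t_tests.empty and not report.anova.empty
        assert "unadjusted" in report.note
        text = report.to_text()
        assert "Two-way ANOVA" in text and "p<0.05" in text

    def test_significance_marks(self):
        assert significance_mark(0.01) == "*"
        assert significance_mark(0.07) == "^"
        assert significance_mark(0.5) == ""
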