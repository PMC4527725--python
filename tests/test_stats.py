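"""Statistical routing, contrasts, mortality modeling, and summaries."""

import numpy as np
import pandas as pd
import pytest

import shockhrv as sh


def make_cohort(rows):
    """rows: (animal_id, group, timepoint, variable, value)."""
    return pd.DataFrame(rows, columns=["animal_id", "group", "timepoint",
                                       "variable", "value"])


def two_group_cohort(s_values, ns_values, variable="MAP", timepoint="Shock30"):
    rows = [(f"S{i:02d}", "S", timepoint, variable, v)
            for i, v in enumerate(s_values)]
    rows += [(f"N{i:02d}", "NS", timepoint, variable, v)
             for i, v in enumerate(ns_values)]
    return make_cohort(rows)


class TestNormalityRouting:
    def test_skewed_sample_routes_nonparametric(self):
        rng = np.random.default_rng(0)
        route = sh.normality_route(rng.exponential(1.0, 200))
        assert not route.parametric

    def test_normal_samples_route_parametric_most_of_the_time(self):
        rng = np.random.default_rng(1)
        hits = [sh.normality_route(rng.normal(70, 8, 13)).parametric
                for _ in range(200)]
        assert np.mean(hits) >= 0.90

    def test_constant_sample_warns_and_routes_nonparametric(self):
        with pytest.warns(UserWarning, match="constant"):
            route = sh.normality_route(np.full(10, 5.0))
        assert not route.parametric

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            sh.normality_route([1.0, 2.0])


class TestWithinGroupTimecourse:
    def timecourse_cohort(self, shift, n=10, sd=3.0, seed=0):
        rng = np.random.default_rng(seed)
        tps = ["Baseline", "Shock30", "Shock60"]
        rows = []
        for i in range(n):
            for j, tp in enumerate(tps):
                v = 70.0 + shift * j + rng.normal(0, sd)
                rows.append((f"S{i:02d}", "S", tp, "MAP", v))
        return make_cohort(rows)

    def test_constant_data_is_not_significant(self):
        res = sh.within_group_timecourse(self.timecourse_cohort(0.0, sd=0.0), "MAP", "S")
        assert res.p_value == 1.0 and res.significant is False

    def test_large_drop_is_detected_with_posthoc(self):
        res = sh.within_group_timecourse(self.timecourse_cohort(-15.0), "MAP", "S")
        assert res.significant
        assert res.test_used in ("rm_anova", "friedman")
        posthoc = dict(res.posthoc)
        assert posthoc[("Baseline", "Shock60")] < 0.05

    def test_null_data_usually_not_significant(self):
        hits = [sh.within_group_timecourse(self.timecourse_cohort(0.0, seed=s),
                                           "MAP", "S").significant
                for s in range(40)]
        assert np.mean(hits) <= 0.2

    def test_guards(self):
        df = self.timecourse_cohort(-15.0, n=2)
        with pytest.raises(ValueError, match="3 animals"):
            sh.within_group_timecourse(df, "MAP", "S")
        df = self.timecourse_cohort(-15.0)
        with pytest.raises(ValueError, match="baseline"):
            sh.within_group_timecourse(df, "MAP", "S", baseline="R0")


class TestBetweenGroupCompare:
    def test_identical_groups_are_not_significant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(60, 8, 13)
        res = sh.between_group_compare(two_group_cohort(x, x[:7]), "MAP", "Shock30")
        assert res.significant is False

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(3)
        df = two_group_cohort(rng.normal(57, 4, 13), rng.normal(43, 4, 7))
        res = sh.between_group_compare(df, "MAP", "Shock30")
        assert res.significant and res.p_value < 0.01
        assert res.test_used in ("t_unpaired", "mann_whitney")

    def test_missing_group_is_skipped_with_reason(self):
        rows = [(f"S{i:02d}", "S", "R60", "MAP", 70.0 + i) for i in range(13)]
        res = sh.between_group_compare(make_cohort(rows), "MAP", "R60")
        assert res.skipped and "NS" in res.reason and "R60" in res.reason
        assert res.p_value is None and res.significant is None

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValueError):
            sh.between_group_compare(two_group_cohort([1, 2], [3, 4]), "MAP", "Nope")


class TestMortalityModel:
    def predictive_cohort(self, seed=0, n_s=13, n_ns=7, effect=14.0):
        rng = np.random.default_rng(seed)
        rows = [(f"S{i:02d}", "S", "Shock30", "MAP", 50.0 + effect + rng.normal(0, 4))
                for i in range(n_s)]
        rows += [(f"N{i:02d}", "NS", "Shock30", "MAP", 50.0 + rng.normal(0, 4))
                 for i in range(n_ns)]
        rows += [(r[0], r[1], "Shock30", "noise", rng.normal(0, 1))
                 for r in rows if r[3] == "MAP"]
        return make_cohort(rows)

    def test_separation_stays_finite_and_discriminates(self):
        model = sh.mortality_model(self.predictive_cohort(effect=30.0),
                                   ["MAP", "noise"], "Shock30")
        assert model.converged
        assert np.all(np.isfinite(model.params["coef"]))
        assert model.auc == pytest.approx(1.0)
        assert "MAP" in model.selected_predictors

    def test_null_predictor_rarely_selected(self):
        hits = []
        for s in range(100):
            model = sh.mortality_model(self.predictive_cohort(seed=s, effect=0.0),
                                       ["MAP", "noise"], "Shock30")
            hits.append(len(model.selected_predictors) > 0)
        # two Holm-adjusted tests at alpha=0.05: familywise error near 5%
        assert np.mean(hits) <= 0.12

    def test_zero_variance_predictor_dropped_with_warning(self):
        df = self.predictive_cohort()
        df.loc[df.variable == "noise", "value"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = sh.mortality_model(df, ["MAP", "noise"], "Shock30")
        assert model.dropped == ["noise"] and model.predictors == ["MAP"]

    def test_ml_path_available(self):
        model = sh.mortality_model(self.predictive_cohort(), ["MAP"], "Shock30",
                                   penalized=False)
        assert model.method == "ml"
        assert np.all(np.isfinite(model.params["p"]))


class TestSummaryTable:
    def test_zero_sd_cells_are_exact(self):
        df = two_group_cohort([57.0] * 13, [43.0] * 7)
        out = sh.summary_table(df)
        s = out[out.group == "S"].iloc[0]
        assert s["mean"] == 57.0 and s["sd"] == 0.0 and s["n"] == 13

    def test_default_cohort_shape(self):
        cohort = sh.generate_cohort(sh.CohortGenParams(seed=0))
        out = sh.summary_table(cohort, ["MAP"])
        counts = out.groupby("group", observed=True)["timepoint"].nunique()
        assert counts["S"] == 10 and counts["NS"] == 6

    def test_single_animal_cell_has_nan_sd(self):
        df = make_cohort([("S00", "S", "Baseline", "MAP", 70.0)])
        out = sh.summary_table(df)
        assert out.iloc[0]["n"] == 1 and np.isnan(out.iloc[0]["sd"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            sh.summary_table(make_cohort([]))


class TestPipeline:
    def test_end_to_end_records_skips_and_contrasts(self):
        res = sh.run_cohort_analysis(variables=["MAP", "HR"], seed=0)
        # 2 variables x 4 attempted contrasts, plus 2 x 4 impossible ones
        assert len(res.comparisons) == 8
        assert len(res.skipped) == 8
        assert all(r.reason for r in res.skipped)
        counts = res.summary[res.summary.variable == "MAP"].groupby(
            "group", observed=True)["timepoint"].nunique()
        assert counts["S"] == 10 and counts["NS"] == 6

    def test_seed_controls_everything(self):
        a = sh.run_cohort_analysis(variables=["MAP"], seed=5)
        b = sh.run_cohort_analysis(variables=["MAP"], seed=5)
        assert a.cohort.equals(b.cohort)
        assert [r.p_value for r in a.comparisons] == [r.p_value for r in b.comparisons]
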