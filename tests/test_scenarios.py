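import numpy as np
import pandas as pd
import pytest

from ncdproj.constants import CAUSES_NCD4
from ncdproj.riskpaf import RISK_FACTORS
from ncdproj.scenarios import (
    ScenarioRule,
    ScenarioSpec,
    adjusted_upod,
    avoidable_deaths,
    baseline_rules,
    compute_pifs,
    counterfactual_exposure,
    get_preset,
    joint_pif_by_cell,
    sdg_achievement,
    subnational_summary,
    tmrel_rules,
    who_target_rules,
)


def exposure_series(risk="smoking", metric="prevalence", start=0.30, slope=0.002,
                    years=range(2001, 2031)):
    return pd.DataFrame([
        {"year": y, "sex": "male", "province": 1, "risk": risk, "metric": metric,
         "value": start + slope * (y - 2015)}
        for y in years
    ])


class TestRules:
    def test_who_rule_count(self):
        spec = who_target_rules(2015)
        assert len(spec.rules) == 6

    def test_smoking_reduction_is_thirty_percent(self):
        assert who_target_rules().rules["smoking"] == ScenarioRule("relative_reduction", 0.30)

    def test_diabetes_and_obesity_halt(self):
        spec = who_target_rules()
        assert spec.rules["diabetes"].kind == "halt_at_baseline"
        assert spec.rules["bmi"].kind == "halt_at_baseline"

    def test_inactivity_ten_salt_thirty(self):
        spec = who_target_rules()
        assert spec.rules["inactivity"].amount == pytest.approx(0.10)
        assert spec.rules["salt"].amount == pytest.approx(0.30)

    def test_bp_twenty_five_percent_on_exceedance(self):
        rule = who_target_rules().rules["blood_pressure"]
        assert rule.amount == pytest.approx(0.25)
        assert rule.exceedance_threshold == 140.0

    def test_unknown_risk_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("x", 2015, rules={"asbestos": ScenarioRule("none")})

    def test_presets(self):
        assert get_preset("who2010").baseline_year == 2010
        assert get_preset("tmrel").rules["salt"].kind == "to_tmrel"
        assert get_preset("baseline").rules == {}
        with pytest.raises(ValueError):
            get_preset("nope")


class TestCounterfactual:
    def test_none_rule_unchanged(self):
        series = exposure_series()
        out = counterfactual_exposure(series, baseline_rules(2015))
        np.testing.assert_array_equal(out["cf_value"].to_numpy(), out["value"].to_numpy())

    def test_halt_freezes_baseline_value(self):
        series = exposure_series(risk="diabetes", start=0.10, slope=0.003)
        spec = ScenarioSpec("halt", 2015, rules={"diabetes": ScenarioRule("halt_at_baseline")})
        out = counterfactual_exposure(series, spec)
        horizon = out[out["year"] == 2030]["cf_value"].iloc[0]
        assert horizon == pytest.approx(0.10, abs=1e-12)

    def test_smoking_thirty_percent_reduction_endpoint(self):
        # 24.3% at the 2015 baseline -> 17.01% at the horizon
        series = exposure_series(risk="smoking", start=0.243, slope=0.0)
        out = counterfactual_exposure(series, who_target_rules(2015))
        horizon = out[out["year"] == 2030]["cf_value"].iloc[0]
        assert horizon == pytest.approx(0.1701, abs=1e-10)

    def test_linear_path_between_baseline_and_horizon(self):
        series = exposure_series(risk="smoking", start=0.30, slope=0.0)
        out = counterfactual_exposure(series, who_target_rules(2015)).set_index("year")
        mid = out.loc[2022, "cf_value"]  # 7/15 of the way down
        assert mid == pytest.approx(0.30 - 0.09 * 7 / 15, abs=1e-12)

    def test_years_before_baseline_untouched(self):
        series = exposure_series(risk="smoking", start=0.30, slope=-0.001)
        out = counterfactual_exposure(series, who_target_rules(2015)).set_index("year")
        for y in range(2001, 2016):
            assert out.loc[y, "cf_value"] == out.loc[y, "value"]

    def test_capped_at_projected_path(self):
        # projected fall faster than the target path: counterfactual must not
        # exceed the projection
        series = exposure_series(risk="smoking", start=0.30, slope=-0.012)
        out = counterfactual_exposure(series, who_target_rules(2015))
        assert (out["cf_value"] <= out["value"] + 1e-12).all()

    def test_missing_baseline_year_errors(self):
        series = exposure_series(years=range(2016, 2031))
        with pytest.raises(ValueError, match="baseline"):
            counterfactual_exposure(series, who_target_rules(2015))

    def test_tmrel_rule_targets_tmrel(self):
        series = exposure_series(risk="salt", metric="mean", start=9.9, slope=-0.05)
        out = counterfactual_exposure(series, tmrel_rules(2015)).set_index("year")
        assert out.loc[2030, "cf_value"] == pytest.approx(RISK_FACTORS["salt"].tmrel_mid)


class TestAvoidableDeaths:
    def _cells(self, deaths=100.0):
        rows = []
        for lo in (30, 35):
            rows.append({"sex": "male", "province": 1, "cause": "CVDs",
                         "age_lo": lo, "age_hi": lo + 5, "deaths": deaths})
        return pd.DataFrame(rows)

    def _pifs(self, values):
        rows = []
        for risk, v in values.items():
            for lo in (30, 35):
                rows.append({"sex": "male", "province": 1, "cause": "CVDs",
                             "age_lo": lo, "age_hi": lo + 5, "risk": risk, "pif": v})
        return pd.DataFrame(rows)

    def test_zero_pif_zero_avoidable(self):
        avd = avoidable_deaths(self._cells(), self._pifs({"smoking": 0.0}))
        assert (avd["avoidable"] == 0.0).all()

    def test_unit_pif_avoids_everything(self):
        avd = avoidable_deaths(self._cells(), self._pifs({"smoking": 1.0}))
        joint = avd[avd["risk"] == "joint"]
        assert joint["avoidable"].sum() == pytest.approx(200.0)

    def test_joint_between_max_and_sum(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = {r: rng.uniform(0, 0.6) for r in ("smoking", "salt", "bmi")}
            avd = avoidable_deaths(self._cells(), self._pifs(vals))
            per_risk = avd[avd["risk"] != "joint"].groupby("risk")["avoidable"].sum()
            joint = avd[avd["risk"] == "joint"]["avoidable"].sum()
            assert joint >= per_risk.max() - 1e-9
            assert joint <= per_risk.sum() + 1e-9

    def test_negative_deaths_rejected(self):
        with pytest.raises(ValueError):
            avoidable_deaths(self._cells(deaths=-5.0), self._pifs({"smoking": 0.1}))

    def test_joint_pif_uses_multiplicative_combination(self):
        pifs = self._pifs({"smoking": 0.5, "salt": 0.5})
        joint = joint_pif_by_cell(pifs)
        assert joint["pif_joint"].tolist() == pytest.approx([0.75, 0.75])


class TestAdjustedUpod:
    def _inputs(self, pif_value):
        deaths, pops, pifs = [], [], []
        for lo in range(30, 70, 5):
            for cause in CAUSES_NCD4:
                deaths.append({"sex": "male", "province": 1, "cause": cause,
                               "age_lo": lo, "age_hi": lo + 5, "deaths": 50.0})
                pifs.append({"sex": "male", "province": 1, "cause": cause,
                             "age_lo": lo, "age_hi": lo + 5, "risk": "smoking",
                             "pif": pif_value})
            pops.append({"sex": "male", "province": 1, "age_lo": lo, "age_hi": lo + 5,
                         "population": 40_000.0})
        return pd.DataFrame(deaths), pd.DataFrame(pops), pd.DataFrame(pifs)

    def test_zero_avoidable_equals_projected(self):
        deaths, pops, pifs = self._inputs(0.0)
        avd = avoidable_deaths(deaths, pifs)
        adj = adjusted_upod(deaths, pops, avd)
        all4 = adj[adj["cause"] == "all4"]["upod"].iloc[0]
        from ncdproj.upod import upod_30_70
        expected = upod_30_70(np.full(8, 200.0 / 40_000.0))
        assert all4 == pytest.approx(expected, rel=1e-12)

    def test_all_avoidable_gives_zero(self):
        deaths, pops, pifs = self._inputs(1.0)
        avd = avoidable_deaths(deaths, pifs)
        adj = adjusted_upod(deaths, pops, avd)
        assert (adj["upod"] == 0.0).all()

    def test_partial_reduction_strictly_lower(self):
        deaths, pops, pifs = self._inputs(0.3)
        avd = avoidable_deaths(deaths, pifs)
        adj = adjusted_upod(deaths, pops, avd)
        deaths2, pops2, pifs2 = self._inputs(0.0)
        base = adjusted_upod(deaths2, pops2, avoidable_deaths(deaths2, pifs2))
        merged = adj.merge(base, on=["sex", "province", "cause"], suffixes=("_adj", "_base"))
        assert (merged["upod_adj"] < merged["upod_base"]).all()


class TestAchievement:
    def test_abstract_2010_pair_achieved(self):
        assert sdg_achievement(0.175, 0.108).achieved

    def test_abstract_2015_pair_not_achieved(self):
        assert not sdg_achievement(0.147, 0.108).achieved

    def test_zero_horizon_always_achieved(self):
        assert sdg_achievement(0.001, 0.0).achieved

    def test_exact_threshold_counts(self):
        assert sdg_achievement(0.15, 0.10).achieved

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            sdg_achievement(1.5, 0.1)

    def test_subnational_counts_match_bruteforce(self):
        rng = np.random.default_rng(2)
        rows = []
        for sex in ("female", "male"):
            for cause in CAUSES_NCD4:
                for province in range(1, 11):
                    rows.append({"sex": sex, "cause": cause, "province": province,
                                 "achieved": bool(rng.random() < 0.5)})
        flags = pd.DataFrame(rows)
        summary = subnational_summary(flags)
        for row in summary.itertuples():
            expected = sum(f["achieved"] for f in rows
                           if f["sex"] == row.sex and f["cause"] == row.cause)
            assert row.achieved_provinces == expected
            assert row.achieved_provinces <= 10

    def test_all_or_none(self):
        flags = pd.DataFrame({"sex": "female", "cause": "CVDs",
                              "province": range(1, 6), "achieved": True})
        assert subnational_summary(flags)["achieved_provinces"].iloc[0] == 5
        flags["achieved"] = False
        assert subnational_summary(flags)["achieved_provinces"].iloc[0] == 0


class TestScenarioIntegration:
    def test_who_rules_never_increase_upod(self, bundle, small_config):
        from ncdproj.projection import (
            project_mortality, project_population, spatiotemporal_interpolate)
        proj = project_mortality(bundle.registry, 2030)
        pop = project_population(bundle.registry, 2030)
        cells = proj[proj["year"] == 2030].merge(
            pop[pop["year"] == 2030], on=["year", "sex", "province", "age_lo", "age_hi"])
        cells["deaths"] = cells["mx"] * cells["population"]
        deaths = cells[["sex", "province", "cause", "age_lo", "age_hi", "deaths"]]
        pop_h = cells[cells["cause"] == "CVDs"][
            ["sex", "province", "age_lo", "age_hi", "population"]]
        dense = spatiotemporal_interpolate(bundle.exposures, 2001, 2030)
        cf = counterfactual_exposure(dense, who_target_rules(2015))
        pifs = compute_pifs(cf, bundle.rr, 2030)
        avd = avoidable_deaths(deaths, pifs)
        adj = adjusted_upod(deaths, pop_h, avd)
        base = adjusted_upod(deaths, pop_h, avoidable_deaths(
            deaths, pifs.assign(pif=0.0)))
        merged = adj.merge(base, on=["sex", "province", "cause"], suffixes=("_who", "_base"))
        assert (merged["upod_who"] <= merged["upod_base"] + 1e-12).all()
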