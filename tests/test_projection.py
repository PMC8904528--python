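import numpy as np
import pandas as pd
import pytest

from ncdproj.constants import ALL_CAUSES
from ncdproj.projection import (
    gpr_smooth,
    project_mortality,
    project_population,
    spatiotemporal_interpolate,
    spline_curve,
    spline_extrapolate,
)
from ncdproj.synthetic import NoiseConfig, SimulationConfig, generate_registry, make_ground_truth


def mean_exposure_frame(values_by_province, years, risk="salt", sex="female", metric="mean"):
    rows = []
    for province, vals in values_by_province.items():
        for y, v in zip(years, vals):
            rows.append({"year": y, "sex": sex, "province": province, "risk": risk,
                         "metric": metric, "value": v, "se": 0.01})
    return pd.DataFrame(rows)


class TestSpatiotemporal:
    years = [2005, 2009, 2011, 2016]

    def test_observed_years_reproduced(self):
        sparse = mean_exposure_frame({1: [9.0, 8.5, 8.4, 8.0], 2: [10.0, 9.6, 9.5, 9.1]},
                                     self.years)
        dense = spatiotemporal_interpolate(sparse, 2001, 2030)
        for row in sparse.itertuples():
            got = dense[(dense["province"] == row.province) & (dense["year"] == row.year)]
            assert got["value"].iloc[0] == pytest.approx(row.value, abs=1e-12)
            assert got["provenance"].iloc[0] == "observed"

    def test_all_years_filled(self):
        sparse = mean_exposure_frame({1: [9.0, 8.5, 8.4, 8.0]}, self.years)
        dense = spatiotemporal_interpolate(sparse, 2001, 2030)
        assert set(dense["year"]) == set(range(2001, 2031))

    def test_province_identical_to_national(self):
        vals = [9.0, 8.5, 8.4, 8.0]
        one = spatiotemporal_interpolate(mean_exposure_frame({1: vals}, self.years), 2001, 2030)
        three = spatiotemporal_interpolate(
            mean_exposure_frame({1: vals, 2: vals, 3: vals}, self.years), 2001, 2030)
        p1 = three[three["province"] == 1].set_index("year")["value"]
        np.testing.assert_allclose(one.set_index("year")["value"].to_numpy(),
                                   p1.to_numpy(), rtol=1e-12)

    def test_linear_truth_recovered_exactly(self):
        line = lambda y: 12.0 - 0.1 * (y - 2005)
        sparse = mean_exposure_frame({1: [line(y) for y in self.years],
                                      2: [line(y) + 0.5 for y in self.years]}, self.years)
        dense = spatiotemporal_interpolate(sparse, 2005, 2016)
        p1 = dense[dense["province"] == 1]
        for row in p1.itertuples():
            assert row.value == pytest.approx(line(row.year), abs=1e-6)

    def test_single_round_errors(self):
        sparse = mean_exposure_frame({1: [9.0]}, [2016])
        with pytest.raises(ValueError, match="round"):
            spatiotemporal_interpolate(sparse, 2001, 2030)

    def test_prevalence_stays_in_unit_interval(self):
        sparse = mean_exposure_frame({1: [0.05, 0.04, 0.035, 0.03]}, self.years,
                                     risk="smoking", metric="prevalence")
        dense = spatiotemporal_interpolate(sparse, 2001, 2050)
        assert ((dense["value"] > 0) & (dense["value"] < 1)).all()


class TestGPR:
    def test_noiseless_interpolates(self):
        df = pd.DataFrame({"year": [2001, 2004, 2008, 2012, 2015],
                           "value": [1.0, 1.4, 1.1, 0.9, 1.2]})
        out = gpr_smooth(df, amplitude=1.0, length_scale=3.0, noise_sd=0.0)
        np.testing.assert_allclose(out["value"].to_numpy(), df["value"].to_numpy(), atol=1e-4)

    def test_constant_input_constant_output(self):
        df = pd.DataFrame({"year": np.arange(2001, 2011), "value": np.full(10, 3.3)})
        out = gpr_smooth(df, amplitude=1.0, length_scale=5.0, noise_sd=0.1)
        np.testing.assert_allclose(out["value"].to_numpy(), 3.3, atol=1e-9)

    def test_matches_closed_form_kernel_solution(self):
        # direct kernel-formula oracle on 5 points
        x = np.array([0.0, 1.0, 2.5, 4.0, 6.0])
        y = np.array([0.2, 0.5, 0.1, -0.3, 0.4])
        amp, ls, noise = 1.3, 2.0, 0.15
        k = lambda a, b: amp**2 * np.exp(-0.5 * (a[:, None] - b[None, :])**2 / ls**2)
        ybar = y.mean()
        K = k(x, x) + noise**2 * np.eye(5)
        expected = ybar + k(x, x) @ np.linalg.solve(K, y - ybar)
        df = pd.DataFrame({"year": x, "value": y})
        out = gpr_smooth(df, amplitude=amp, length_scale=ls, noise_sd=noise)
        np.testing.assert_allclose(out["value"].to_numpy(), expected, atol=1e-8)

    def test_rejects_bad_hyperparameters(self):
        df = pd.DataFrame({"year": [1, 2, 3], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            gpr_smooth(df, amplitude=0.0)
        with pytest.raises(ValueError):
            gpr_smooth(df, length_scale=-1.0)


class TestSpline:
    def test_linear_input_linear_everywhere(self):
        x = np.array([2001.0, 2005.0, 2010.0, 2015.0])
        y = 2.0 + 0.3 * (x - 2001)
        xn = np.arange(1995, 2031, dtype=float)
        out = spline_curve(x, y, xn)
        np.testing.assert_allclose(out, 2.0 + 0.3 * (xn - 2001), atol=1e-9)

    def test_observed_years_reproduced(self):
        cov = pd.DataFrame({"year": [2001, 2005, 2010, 2015], "province": 1,
                            "covariate": "wealth_index", "value": [0.4, 0.5, 0.65, 0.8]})
        out = spline_extrapolate(cov, 2030)
        obs = out[out["provenance"] == "observed"].set_index("year")["value"]
        for y, v in zip(cov["year"], cov["value"]):
            assert obs.loc[y] == pytest.approx(v, abs=1e-12)

    def test_quadratic_extrapolated_linearly_at_boundary_slope(self):
        x = np.linspace(2001, 2015, 8)
        y = (x - 2001) ** 2
        from scipy.interpolate import CubicSpline
        cs = CubicSpline(x, y, bc_type="natural")
        slope = cs(x[-1], 1)
        out = spline_curve(x, y, np.array([2016.0, 2020.0, 2030.0]))
        expected = y[-1] + slope * (np.array([2016.0, 2020.0, 2030.0]) - x[-1])
        np.testing.assert_allclose(out, expected, rtol=1e-12)
        # linear tail: zero second differences
        tail = spline_curve(x, y, np.array([2016.0, 2017.0, 2018.0]))
        assert np.diff(tail, 2) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="4"):
            spline_curve(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]), np.array([4.0]))

    def test_urbanization_clamped(self):
        cov = pd.DataFrame({"year": [2001, 2005, 2010, 2015], "province": 1,
                            "covariate": "urbanization_pct", "value": [70, 80, 90, 99]})
        out = spline_extrapolate(cov, 2040)
        assert out["value"].max() <= 100.0


class TestMortalityProjection:
    def _config(self, slope, seed=3):
        return SimulationConfig(
            n_provinces=2, seed=seed,
            mortality_slope={c: slope for c in ALL_CAUSES},
            noise=NoiseConfig(deaths=False, surveys=False),
            province_effect_sd=0.0,
        )

    def test_zero_slope_projects_observed_mean(self):
        cfg = self._config(0.0)
        surf = generate_registry(cfg)
        proj = project_mortality(surf, 2030)
        at_horizon = proj[(proj["year"] == 2030) & (proj["sex"] == "male")
                          & (proj["cause"] == "CVDs") & (proj["province"] == 1)]
        obs = surf.data[(surf.data["sex"] == "male") & (surf.data["cause"] == "CVDs")
                        & (surf.data["province"] == 1)]
        obs_rate = (obs.groupby("age_lo")
                    .apply(lambda g: (g["deaths"] / g["population"]).mean(),
                           include_groups=False))
        got = at_horizon.set_index("age_lo")["mx"]
        np.testing.assert_allclose(got.to_numpy(), obs_rate.loc[got.index].to_numpy(),
                                   rtol=0.05)

    def test_known_trend_recovered(self):
        # -2%/yr log-trend recovered within 15% relative error at 2030 (median)
        errors = []
        for rep in range(20):
            cfg = SimulationConfig(n_provinces=2, seed=50 + rep,
                                   mortality_slope={c: -0.02 for c in ALL_CAUSES})
            surf = generate_registry(cfg)
            truth = make_ground_truth(cfg)
            proj = project_mortality(surf, 2030)
            got = proj[(proj["year"] == 2030) & (proj["sex"] == "female")
                       & (proj["cause"] == "CVDs") & (proj["province"] == 1)
                       & (proj["age_lo"] == 60)]["mx"].iloc[0]
            true = float(truth.mortality_rate(cfg, 2030, "female", 1, "CVDs", 62.5))
            errors.append(abs(got - true) / true)
        assert np.median(errors) < 0.15

    def test_national_matches_weighted_provinces(self, bundle):
        proj = project_mortality(bundle.registry, 2030)
        pop = project_population(bundle.registry, 2030)
        cells = proj[proj["year"] == 2030].merge(pop[pop["year"] == 2030],
                                                 on=["year", "sex", "province", "age_lo", "age_hi"])
        sub = cells[(cells["sex"] == "male") & (cells["cause"] == "CVDs")]
        national = (sub["mx"] * sub["population"]).sum() / sub["population"].sum()
        oracle = sum(r.mx * r.population for r in sub.itertuples()) / sub["population"].sum()
        assert national == pytest.approx(oracle, rel=1e-12)

    def test_requires_eight_years(self):
        cfg = SimulationConfig(n_provinces=2, seed=1, years_observed=(2010, 2015))
        surf = generate_registry(cfg)
        with pytest.raises(ValueError, match="8"):
            project_mortality(surf, 2030)

    def test_all_zero_stratum_projected_zero(self, caplog):
        cfg = self._config(0.0)
        surf = generate_registry(cfg)
        df = surf.data.copy()
        mask = (df["sex"] == "female") & (df["cause"] == "diabetes_mellitus") \
            & (df["province"] == 1)
        df.loc[mask, "deaths"] = 0
        from ncdproj.upod import MortalitySurface
        proj = project_mortality(MortalitySurface(df), 2030)
        got = proj[(proj["sex"] == "female") & (proj["cause"] == "diabetes_mellitus")
                   & (proj["province"] == 1) & (proj["year"] == 2030)]
        assert (got["mx"] == 0.0).all()

    def test_rates_positive(self, bundle):
        proj = project_mortality(bundle.registry, 2030)
        assert (proj["mx"] >= 0).all()

    def test_population_projection_recovers_growth(self, small_config, truth):
        pop = project_population(generate_registry(small_config, truth), 2030)
        got = pop[(pop["year"] == 2030) & (pop["sex"] == "male")
                  & (pop["province"] == 1) & (pop["age_lo"] == 40)]["population"].iloc[0]
        true = float(truth.population(small_config, 2030, "male", 1, 42.5))
        assert got == pytest.approx(true, rel=1e-6)
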