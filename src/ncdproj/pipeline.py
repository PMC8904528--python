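"""End-to-end orchestration: simulate -> project -> scenario -> report.

Stages run in workflow order; every output CSV is written with a stable
row order and accompanied by run metadata (seed, config hash), so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CAUSES_NCD4, RISKS, SEXES
from .io import config_hash, validate_inputs, write_table
from .lifetable import build_life_table, cause_deleted_table, temporary_life_expectancy
from .projection import (
    BMAConfig,
    fit_bma,
    project_bma,
    project_mortality,
    project_population,
    spatiotemporal_interpolate,
)
from .scenarios import (
    adjusted_upod,
    avoidable_deaths,
    compute_pifs,
    counterfactual_exposure,
    get_preset,
    sdg_achievement,
    subnational_summary,
)
from .synthetic import SimulationConfig, generate_all
from .upod import upod_30_70, upod_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

BMA_COVARIATES = tuple(RISKS) + ("wealth_index", "schooling_years", "urbanization_pct", "population")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    scenario: str = "who2015"
    seed: int = 0
    n_provinces: int = 31
    horizon_year: int = 2030
    by_province: bool = True
    bma_draws: int = 500

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(n_provinces=self.n_provinces,
                                horizon_year=self.horizon_year, seed=self.seed)


@dataclass
class PipelineResult:
    upod_observed: pd.DataFrame
    upod_projected: pd.DataFrame
    upod_bma: pd.DataFrame
    avoidable: pd.DataFrame | None
    upod_adjusted: pd.DataFrame | None
    achievement: pd.DataFrame
    summary: pd.DataFrame
    life_expectancy: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def _upod_from_cells(cells: pd.DataFrame, rate_col: str, keys: list[str]) -> pd.DataFrame:
    rows = []
    for key, grp in cells.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        g = grp.sort_values("age_lo")
        rows.append(dict(zip(keys, key)) |
                    {"upod": upod_30_70(g[rate_col].to_numpy(), age_lo=g["age_lo"].to_numpy())})
    return pd.DataFrame(rows)


def _national_exposure(dense: pd.DataFrame) -> pd.DataFrame:
    """Year-indexed design frame of the ten candidate covariates."""
    nat = (dense.groupby(["risk", "year"])["value"].mean()
           .unstack("risk").rename_axis(columns=None))
    return nat


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full comparative-risk workflow on synthetic inputs."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()
    spec = get_preset(config.scenario)
    spec = type(spec)(name=spec.name, baseline_year=spec.baseline_year,
                      horizon_year=config.horizon_year, rules=spec.rules)

    _stage("simulate")
    bundle = generate_all(sim)
    registry, exposures, rr, covariates = (bundle.registry, bundle.exposures,
                                           bundle.rr, bundle.covariates)
    report = validate_inputs({"registry": registry, "exposures": exposures, "rr": rr})
    if not report.ok:
        raise RuntimeError(f"stage simulate produced invalid inputs:\n{report}")
    write_table(registry.data, out / "registry.csv")
    write_table(exposures, out / "exposures.csv")
    write_table(rr, out / "rr.csv")
    write_table(covariates, out / "covariates.csv")

    _stage("upod-observed")
    by = ("year", "sex", "province") if config.by_province else ("year", "sex")
    upod_obs = upod_table(registry, causes=CAUSES_NCD4, by=by)
    upod_nat = upod_table(registry, causes=CAUSES_NCD4, by=("year", "sex"))
    upod_nat["province"] = "national"
    upod_obs = pd.concat([upod_obs, upod_nat], ignore_index=True)
    write_table(upod_obs.sort_values(["year", "sex", "province"], key=lambda s: s.astype(str)),
                out / "upod_observed.csv")

    _stage("project-mortality")
    rates_proj = project_mortality(registry, config.horizon_year)
    pop_proj = project_population(registry, config.horizon_year)
    write_table(rates_proj[rates_proj["provenance"] == "projected"],
                out / "mortality_projected.csv")

    _stage("project-exposures")
    year0 = sim.years_observed[0]
    dense = spatiotemporal_interpolate(exposures, year0, config.horizon_year)
    write_table(dense, out / "exposures_projected.csv")

    _stage("project-upod-bma")
    nat_cov = _national_exposure(dense)
    for cov in ("wealth_index", "schooling_years", "urbanization_pct"):
        series = covariates[covariates["covariate"] == cov].groupby("year")["value"].mean()
        nat_cov[cov] = series
    nat_cov["population"] = (covariates[covariates["covariate"] == "population"]
                             .groupby("year")["value"].sum())
    bma_cfg = BMAConfig(covariate_labels=BMA_COVARIATES, sampler="enumerate",
                        transform="logit", seed=config.seed)
    bma_rows = []
    observed_years = list(sim.years)
    for sex in SEXES + ("both",):
        sub = upod_nat if sex == "both" else upod_nat[upod_nat["sex"] == sex]
        if sex == "both":
            pooled = upod_table(registry, causes=CAUSES_NCD4, by=("year",))
            series = pooled.set_index("year")["upod"].loc[observed_years]
        else:
            series = sub.set_index("year")["upod"].loc[observed_years]
        fit = fit_bma(series, nat_cov, bma_cfg)
        proj = project_bma(fit, nat_cov, config.horizon_year, draws=config.bma_draws,
                           seed=config.seed)
        proj = proj.reset_index()
        proj["sex"] = sex
        bma_rows.append(proj)
    upod_bma = pd.concat(bma_rows, ignore_index=True)
    write_table(upod_bma, out / "upod_bma_projection.csv")

    _stage("horizon-cells")
    horizon = config.horizon_year
    cells = rates_proj[rates_proj["year"] == horizon].merge(
        pop_proj[pop_proj["year"] == horizon],
        on=["year", "sex", "province", "age_lo", "age_hi"])
    cells["deaths"] = cells["mx"] * cells["population"]
    proj_deaths = cells[["sex", "province", "cause", "age_lo", "age_hi", "deaths"]]
    pop_h = (cells[cells["cause"] == cells["cause"].iloc[0]]
             [["sex", "province", "age_lo", "age_hi", "population"]])
    upod_proj = _upod_from_cells(
        cells[cells["cause"].isin(CAUSES_NCD4)]
        .groupby(["sex", "province", "age_lo", "age_hi"], as_index=False)["mx"].sum(),
        "mx", ["sex", "province"])
    upod_proj["cause"] = "all4"
    upod_proj_cause = _upod_from_cells(cells[cells["cause"].isin(CAUSES_NCD4)],
                                       "mx", ["sex", "province", "cause"])
    upod_proj = pd.concat([upod_proj, upod_proj_cause], ignore_index=True)
    write_table(upod_proj, out / "upod_projected_horizon.csv")

    null_scenario = all(spec.rule(r).kind == "none" for r in RISKS)
    avoidable = None
    adj = None
    if not null_scenario:
        _stage("scenario")
        cf = counterfactual_exposure(dense, spec)
        pifs = compute_pifs(cf, rr, horizon)
        avoidable = avoidable_deaths(proj_deaths, pifs)
        agg = (avoidable.groupby(["sex", "cause", "risk"], as_index=False)["avoidable"].sum())
        agg["scenario"] = spec.name
        write_table(agg, out / "avoidable_deaths.csv")
        adj = adjusted_upod(proj_deaths, pop_h, avoidable)
        write_table(adj, out / "upod_adjusted.csv")

    _stage("achievement")
    base_by_cause = []
    for cause in CAUSES_NCD4:
        tab = upod_table(registry, causes=(cause,), by=("year", "sex", "province"))
        tab["cause"] = cause
        base_by_cause.append(tab)
        nat = upod_table(registry, causes=(cause,), by=("year", "sex"))
        nat["province"] = "national"
        nat["cause"] = cause
        base_by_cause.append(nat)
    all4 = upod_obs.copy()
    all4["cause"] = "all4"
    baseline_upod = pd.concat(base_by_cause + [all4], ignore_index=True)
    baseline_upod = baseline_upod[baseline_upod["year"] == spec.baseline_year]

    horizon_upod = adj if adj is not None else upod_proj
    nat_cells = (cells.groupby(["sex", "cause", "age_lo", "age_hi"], as_index=False)
                 [["deaths", "population"]].sum())
    nat_cells["mx"] = nat_cells["deaths"] / nat_cells["population"]
    nat_rows = _upod_from_cells(nat_cells[nat_cells["cause"].isin(CAUSES_NCD4)],
                                "mx", ["sex", "cause"])
    nat_rows["province"] = "national"
    nat_all4 = _upod_from_cells(
        nat_cells[nat_cells["cause"].isin(CAUSES_NCD4)]
        .groupby(["sex", "age_lo", "age_hi"], as_index=False)
        .agg(mx=("mx", "sum")), "mx", ["sex"])
    nat_all4["province"] = "national"
    nat_all4["cause"] = "all4"
    if adj is not None:
        nat_adj = _adjusted_national(proj_deaths, pop_h, avoidable)
        horizon_upod = pd.concat([adj, nat_adj], ignore_index=True)
    else:
        horizon_upod = pd.concat([upod_proj, nat_rows, nat_all4], ignore_index=True)

    flags = []
    merged = baseline_upod.merge(horizon_upod, on=["sex", "province", "cause"],
                                 suffixes=("_base", "_horizon"))
    for row in merged.itertuples():
        flag = sdg_achievement(row.upod_base, row.upod_horizon)
        flags.append({"scenario": spec.name, "sex": row.sex, "province": row.province,
                      "cause": row.cause, "upod_baseline": row.upod_base,
                      "upod_horizon": row.upod_horizon, "achieved": flag.achieved})
    achievement = pd.DataFrame(flags)
    write_table(achievement, out / "achievement.csv")
    summary = subnational_summary(
        achievement[achievement["province"] != "national"])
    write_table(summary, out / "subnational_summary.csv")

    _stage("life-expectancy")
    life = _life_expectancy_tables(registry, cells, avoidable, spec, sim)
    write_table(life, out / "life_expectancy.csv")

    meta = {
        "seed": config.seed,
        "scenario": spec.name,
        "baseline_year": spec.baseline_year,
        "horizon_year": config.horizon_year,
        "n_provinces": config.n_provinces,
        "config_hash": config_hash(asdict(config)),
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    with open(out / "metadata.json", "w") as fh:
        json.dump({k: v for k, v in meta.items() if k != "runtime_s"}, fh, indent=2,
                  sort_keys=True)
    logger.info("pipeline finished in %.1fs", meta["runtime_s"])
    return PipelineResult(upod_observed=upod_obs, upod_projected=upod_proj,
                          upod_bma=upod_bma, avoidable=avoidable, upod_adjusted=adj,
                          achievement=achievement, summary=summary, life_expectancy=life,
                          metadata=meta)


def _adjusted_national(proj_deaths: pd.DataFrame, pop_h: pd.DataFrame,
                       avoidable: pd.DataFrame) -> pd.DataFrame:
    keys = ["sex", "province", "cause", "age_lo", "age_hi"]
    joint = avoidable[avoidable["risk"] == "joint"][keys + ["avoidable"]]
    cells = proj_deaths.merge(joint, on=keys, how="left")
    cells["avoidable"] = cells["avoidable"].fillna(0.0)
    cells["remaining"] = cells["deaths"] - cells["avoidable"]
    cells = cells.merge(pop_h, on=["sex", "province", "age_lo", "age_hi"])
    nat = cells.groupby(["sex", "cause", "age_lo", "age_hi"], as_index=False)[
        ["remaining", "population"]].sum()
    nat["mx"] = nat["remaining"] / nat["population"]
    out = _upod_from_cells(nat[nat["cause"].isin(CAUSES_NCD4)], "mx", ["sex", "cause"])
    out["province"] = "national"
    pooled = (nat[nat["cause"].isin(CAUSES_NCD4)]
              .groupby(["sex", "age_lo", "age_hi"], as_index=False).agg(mx=("mx", "sum")))
    all4 = _upod_from_cells(pooled, "mx", ["sex"])
    all4["province"] = "national"
    all4["cause"] = "all4"
    return pd.concat([out, all4], ignore_index=True)


def _life_expectancy_tables(registry, cells: pd.DataFrame, avoidable, spec,
                            sim: SimulationConfig) -> pd.DataFrame:
    """Temporary 30-70 life expectancy and per-cause deletion gains."""
    rows = []
    last_obs = sim.years_observed[1]
    for sex in SEXES:
        obs = registry.rates(sex=sex, year=last_obs).sort_values("age_lo")
        lt = build_life_table(obs[["age_lo", "age_hi", "mx"]])
        rows.append({"sex": sex, "year": last_obs, "cause_deleted": "", "scenario": "observed",
                     "e30_70": temporary_life_expectancy(lt)})

        nat = (cells[cells["sex"] == sex]
               .groupby(["cause", "age_lo", "age_hi"], as_index=False)[["deaths", "population"]]
               .sum())
        allc = nat.groupby(["age_lo", "age_hi"], as_index=False).agg(
            deaths=("deaths", "sum"), population=("population", "first"))
        allc["mx"] = allc["deaths"] / allc["population"]
        lt_h = build_life_table(allc[["age_lo", "age_hi", "mx"]])
        e_h = temporary_life_expectancy(lt_h)
        rows.append({"sex": sex, "year": int(cells["year"].iloc[0]), "cause_deleted": "",
                     "scenario": "projected", "e30_70": e_h})

        if avoidable is not None:
            joint = avoidable[(avoidable["risk"] == "joint") & (avoidable["sex"] == sex)]
            nat_avd = joint.groupby(["cause", "age_lo", "age_hi"], as_index=False)[
                "avoidable"].sum()
            adj_cells = nat.merge(nat_avd, on=["cause", "age_lo", "age_hi"], how="left")
            adj_cells["avoidable"] = adj_cells["avoidable"].fillna(0.0)
            adj_cells["remaining"] = adj_cells["deaths"] - adj_cells["avoidable"]
            adj_all = adj_cells.groupby(["age_lo", "age_hi"], as_index=False).agg(
                remaining=("remaining", "sum"), population=("population", "first"))
            adj_all["mx"] = adj_all["remaining"] / adj_all["population"]
            lt_adj = build_life_table(adj_all[["age_lo", "age_hi", "mx"]])
            e_adj = temporary_life_expectancy(lt_adj)
            rows.append({"sex": sex, "year": int(cells["year"].iloc[0]), "cause_deleted": "",
                         "scenario": spec.name, "e30_70": e_adj})
            for cause in CAUSES_NCD4:
                frac = adj_cells[adj_cells["cause"] == cause].sort_values("age_lo")
                total = adj_all.sort_values("age_lo")
                r = (frac["remaining"].to_numpy() / total["remaining"].to_numpy())
                lt_del = cause_deleted_table(lt_adj, np.clip(r, 0, 1))
                rows.append({"sex": sex, "year": int(cells["year"].iloc[0]),
                             "cause_deleted": cause, "scenario": spec.name,
                             "e30_70": temporary_life_expectancy(lt_del),
                             "gain": temporary_life_expectancy(lt_del) - e_adj})
    return pd.DataFrame(rows)
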