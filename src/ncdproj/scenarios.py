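"""Counterfactual exposure scenarios, avoidable deaths and SDG 3.4 flags.

A scenario fixes a baseline year and a per-risk rule: a relative reduction
of the exposure level, a freeze at the baseline level ("halt"), a shift to
the theoretical-minimum exposure, or no change.  Counterfactual
trajectories run linearly from the baseline-year level to the horizon
target and are capped at the projected trajectory, so a scenario can never
worsen an exposure that is already falling faster than its target.

Avoidable deaths are ``PIF x projected deaths`` per (sex, cause, province,
age) cell, combined across risks with the multiplicative joint fraction;
subtracting them from projected deaths and rebuilding rates yields the
scenario-adjusted 40q30.  A stratum achieves SDG 3.4 when the horizon
40q30 is at most two thirds of its baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constants import CAUSES_NCD4, METRIC_PREVALENCE, RR_CATEGORICAL
from .riskpaf import RISK_FACTORS, joint_paf, pif, pif_continuous
from .upod import upod_30_70

__all__ = [
    "ScenarioRule",
    "ScenarioSpec",
    "AchievementFlag",
    "who_target_rules",
    "tmrel_rules",
    "baseline_rules",
    "get_preset",
    "counterfactual_exposure",
    "compute_pifs",
    "joint_pif_by_cell",
    "avoidable_deaths",
    "adjusted_upod",
    "sdg_achievement",
    "subnational_summary",
]

RULE_KINDS = ("relative_reduction", "halt_at_baseline", "to_tmrel", "none")

#: raised-exposure threshold used when a prevalence-style target is applied
#: to a continuous mean (reduction acts on the mass above the threshold)
EXCEEDANCE_THRESHOLDS = {"blood_pressure": 140.0}


@dataclass(frozen=True)
class ScenarioRule:
    kind: str
    amount: float = 0.0
    exceedance_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if not 0.0 <= self.amount <= 1.0:
            raise ValueError("reduction fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    baseline_year: int
    horizon_year: int = 2030
    rules: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.rules) - set(RISK_FACTORS)
        if unknown:
            raise ValueError(f"rules given for unknown risks {sorted(unknown)}")

    def rule(self, risk: str) -> ScenarioRule:
        return self.rules.get(risk, ScenarioRule("none"))


@dataclass(frozen=True)
class AchievementFlag:
    stratum: dict
    upod_baseline: float
    upod_horizon: float
    achieved: bool


def who_target_rules(baseline_year: int = 2015, horizon_year: int = 2030) -> ScenarioSpec:
    """The six global monitoring-framework targets for the modelled risks.

    Raised blood pressure: 25% relative reduction (applied to the mass of
    the mean-exposure distribution above the raised threshold); diabetes
    and obesity: halt the rise at the baseline level; physical inactivity:
    10% reduction; smoking: 30% reduction; mean salt intake: 30% reduction.
    """
    return ScenarioSpec(
        name=f"who{baseline_year}",
        baseline_year=baseline_year,
        horizon_year=horizon_year,
        rules={
            "blood_pressure": ScenarioRule("relative_reduction", 0.25,
                                           EXCEEDANCE_THRESHOLDS["blood_pressure"]),
            "diabetes": ScenarioRule("halt_at_baseline"),
            "bmi": ScenarioRule("halt_at_baseline"),
            "inactivity": ScenarioRule("relative_reduction", 0.10),
            "smoking": ScenarioRule("relative_reduction", 0.30),
            "salt": ScenarioRule("relative_reduction", 0.30),
        },
    )


def tmrel_rules(baseline_year: int = 2015, horizon_year: int = 2030) -> ScenarioSpec:
    """All risks shifted to their theoretical-minimum exposure levels."""
    return ScenarioSpec(
        name="tmrel", baseline_year=baseline_year, horizon_year=horizon_year,
        rules={risk: ScenarioRule("to_tmrel") for risk in RISK_FACTORS},
    )


def baseline_rules(baseline_year: int = 2015, horizon_year: int = 2030) -> ScenarioSpec:
    """Null scenario: every exposure keeps its projected trajectory."""
    return ScenarioSpec(name="baseline", baseline_year=baseline_year,
                        horizon_year=horizon_year, rules={})


_PRESETS = {
    "who2010": lambda: who_target_rules(2010),
    "who2015": lambda: who_target_rules(2015),
    "tmrel": lambda: tmrel_rules(),
    "baseline": lambda: baseline_rules(),
}


def get_preset(name: str) -> ScenarioSpec:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown scenario preset {name!r}; options: {sorted(_PRESETS)}")


def _horizon_target(risk: str, rule: ScenarioRule, baseline_value: float) -> float:
    spec = RISK_FACTORS[risk]
    if rule.kind == "halt_at_baseline":
        return baseline_value
    if rule.kind == "to_tmrel":
        return 0.0 if spec.exposure_kind == METRIC_PREVALENCE else spec.tmrel_mid
    if rule.kind == "relative_reduction":
        if rule.exceedance_threshold is not None and spec.exposure_kind != METRIC_PREVALENCE:
            # reduce P(X > threshold) by the stated fraction via a mean shift
            thr, sd = rule.exceedance_threshold, spec.dist_sd
            p_exceed = norm.sf(thr, loc=baseline_value, scale=sd)
            target_p = np.clip((1.0 - rule.amount) * p_exceed, 1e-12, 1 - 1e-12)
            return float(thr - sd * norm.ppf(1.0 - target_p))
        return (1.0 - rule.amount) * baseline_value
    return baseline_value  # "none" never reaches here


def counterfactual_exposure(projected: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Counterfactual exposure trajectories under a scenario.

    ``projected`` is a dense exposure table (year, sex, province, risk,
    metric, value).  Values at or before the baseline year are untouched;
    from the baseline to the horizon the counterfactual runs linearly from
    the baseline-year level to the rule's horizon target, capped at the
    projected value so reductions never push exposure above its projected
    path.
    """
    out = projected.copy()
    out["cf_value"] = out["value"].astype(float)
    for (risk, sex, province), grp in projected.groupby(["risk", "sex", "province"]):
        rule = spec.rule(risk)
        if rule.kind == "none":
            continue
        base_rows = grp.loc[grp["year"] == spec.baseline_year, "value"]
        if base_rows.empty:
            raise ValueError(
                f"baseline year {spec.baseline_year} missing for ({risk}, {sex}, {province})")
        v_base = float(base_rows.iloc[0])
        target = _horizon_target(risk, rule, v_base)
        span = spec.horizon_year - spec.baseline_year
        sel = (grp["year"] > spec.baseline_year) & (grp["year"] <= spec.horizon_year)
        yrs = grp.loc[sel, "year"].to_numpy(dtype=float)
        frac = (yrs - spec.baseline_year) / span  # hits 1.0 exactly at horizon
        path = v_base + (target - v_base) * frac
        capped = np.minimum(path, grp.loc[sel, "value"].to_numpy(dtype=float))
        if RISK_FACTORS[risk].exposure_kind == METRIC_PREVALENCE:
            capped = np.clip(capped, 0.0, 1.0)
        out.loc[grp.index[sel], "cf_value"] = capped
    return out


def compute_pifs(exposures: pd.DataFrame, rr: pd.DataFrame, year: int) -> pd.DataFrame:
    """Per-risk impact fractions per (sex, province, cause, age band).

    ``exposures`` must carry both ``value`` (projected) and ``cf_value``
    (counterfactual) columns; ``rr`` is the relative-risk table.  Rows are
    produced only for admissible risk-cause pairs present in the table.
    """
    snap = exposures[exposures["year"] == year]
    if snap.empty:
        raise ValueError(f"no exposure rows at year {year}")
    rows = []
    for row in snap.itertuples():
        spec = RISK_FACTORS[row.risk]
        rr_rows = rr[(rr["risk"] == row.risk) & (rr["sex"] == row.sex)]
        for rr_row in rr_rows.itertuples():
            if rr_row.kind == RR_CATEGORICAL:
                val = pif(row.value, row.cf_value, rr_row.rr)
            else:
                val = pif_continuous(row.value, row.cf_value, spec.dist_sd,
                                     spec, rr_row.rr, grid=401)
            rows.append({
                "sex": row.sex, "province": row.province, "cause": rr_row.cause,
                "age_lo": rr_row.age_lo, "age_hi": rr_row.age_hi,
                "risk": row.risk, "pif": max(val, 0.0),
            })
    return pd.DataFrame(rows)


def joint_pif_by_cell(pifs: pd.DataFrame) -> pd.DataFrame:
    """Multiplicative joint fraction per (sex, province, cause, age band)."""
    keys = ["sex", "province", "cause", "age_lo", "age_hi"]
    return (pifs.groupby(keys)["pif"]
            .apply(lambda s: joint_paf(s.to_numpy()))
            .reset_index(name="pif_joint"))


def avoidable_deaths(projected_deaths: pd.DataFrame, pifs: pd.DataFrame) -> pd.DataFrame:
    """``PIF x projected deaths`` per cell, per risk and for the joint effect.

    ``projected_deaths`` has (sex, province, cause, age_lo, age_hi, deaths)
    rows at the horizon year.  Returns cell-level avoidable counts with a
    ``risk`` column that includes the pseudo-risk ``joint``.
    """
    if (projected_deaths["deaths"] < 0).any():
        raise ValueError("projected deaths must be non-negative")
    if ((pifs["pif"] < 0) | (pifs["pif"] > 1)).any():
        raise ValueError("impact fractions must lie in [0, 1]")
    keys = ["sex", "province", "cause", "age_lo", "age_hi"]
    per_risk = pifs.merge(projected_deaths, on=keys)
    per_risk["avoidable"] = per_risk["pif"] * per_risk["deaths"]
    joint = joint_pif_by_cell(pifs).merge(projected_deaths, on=keys)
    joint["avoidable"] = joint["pif_joint"] * joint["deaths"]
    joint["risk"] = "joint"
    cols = keys + ["risk", "avoidable"]
    return pd.concat([per_risk[cols], joint[cols]], ignore_index=True)


def adjusted_upod(projected_deaths: pd.DataFrame, population: pd.DataFrame,
                  avoidable: pd.DataFrame, causes=CAUSES_NCD4) -> pd.DataFrame:
    """Recompute 40q30 after subtracting joint avoidable deaths per cell.

    ``population`` has (sex, province, age_lo, age_hi, population) at the
    horizon year.  Returns one row per (sex, province, cause) plus pooled
    all-cause-of-interest rows (cause = "all4").
    """
    keys = ["sex", "province", "cause", "age_lo", "age_hi"]
    joint = avoidable[avoidable["risk"] == "joint"][keys + ["avoidable"]]
    cells = projected_deaths.merge(joint, on=keys, how="left")
    cells["avoidable"] = cells["avoidable"].fillna(0.0)
    if ((cells["avoidable"] - cells["deaths"]) > 1e-9).any():
        raise ValueError("avoidable deaths exceed projected deaths in some cell")
    cells["remaining"] = cells["deaths"] - cells["avoidable"]
    cells = cells[cells["cause"].isin(list(causes))]
    cells = cells.merge(population, on=["sex", "province", "age_lo", "age_hi"])

    rows = []
    for (sex, province, cause), grp in cells.groupby(["sex", "province", "cause"]):
        g = grp.sort_values("age_lo")
        rows.append({"sex": sex, "province": province, "cause": cause,
                     "upod": upod_30_70(g["remaining"].to_numpy() / g["population"].to_numpy(),
                                        age_lo=g["age_lo"].to_numpy())})
    pooled = cells.groupby(["sex", "province", "age_lo", "age_hi"], as_index=False).agg(
        remaining=("remaining", "sum"), population=("population", "first"))
    for (sex, province), grp in pooled.groupby(["sex", "province"]):
        g = grp.sort_values("age_lo")
        rows.append({"sex": sex, "province": province, "cause": "all4",
                     "upod": upod_30_70(g["remaining"].to_numpy() / g["population"].to_numpy(),
                                        age_lo=g["age_lo"].to_numpy())})
    return pd.DataFrame(rows)


def sdg_achievement(upod_baseline: float, upod_horizon: float,
                    stratum: dict | None = None) -> AchievementFlag:
    """One-third-reduction test: achieved iff horizon <= (2/3) * baseline."""
    for v in (upod_baseline, upod_horizon):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    # exact 2/3 factor; the epsilon only guards binary floating point when
    # the ratio is mathematically exactly two thirds
    return AchievementFlag(
        stratum=stratum or {},
        upod_baseline=upod_baseline,
        upod_horizon=upod_horizon,
        achieved=bool(upod_horizon <= (2.0 / 3.0) * upod_baseline + 1e-12),
    )


def subnational_summary(flags: pd.DataFrame) -> pd.DataFrame:
    """Count achieving provinces per (sex, cause[, scenario])."""
    keys = [k for k in ("scenario", "sex", "cause") if k in flags.columns]
    out = flags.groupby(keys, as_index=False).agg(
        achieved_provinces=("achieved", "sum"), provinces=("achieved", "size"))
    out["achieved_provinces"] = out["achieved_provinces"].astype(int)
    return out
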