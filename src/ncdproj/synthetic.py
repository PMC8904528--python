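"""Synthetic registry, survey, relative-risk and covariate inputs.

Generates the full input bundle for the pipeline with known ground-truth
trends, so every downstream stage can be tested by parameter recovery
without any external data:

* a 2001-2015 death-registry-style table with log-linear declining
  cause-specific mortality, a Gompertz-like age gradient, mean-zero
  Gaussian province intercepts and Poisson count noise;
* sparse survey rounds (2005/2009/2011/2016) of six risk-factor exposures,
  logistic trends for prevalences and linear trends for means, with
  binomial / normal sampling noise;
* an age- and sex-graded relative-risk table restricted to the admissible
  risk-cause pairings;
* smooth province-level covariate series (wealth index, schooling,
  urbanization, population) through the horizon year.

National exposure levels are anchored so that 2010/2015 values, and the
2015 national 40q30, sit near published magnitudes for Iran; the package
makes no claim of reproducing actual registry counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .constants import (
    AGE_BANDS_30_70,
    ALL_CAUSES,
    ALLOWED_RISK_CAUSE,
    COVARIATE_COLUMNS,
    EXPOSURE_COLUMNS,
    METRIC_MEAN,
    METRIC_PREVALENCE,
    REGISTRY_COLUMNS,
    RISKS,
    RR_CATEGORICAL,
    RR_PER_UNIT,
    SEXES,
)
from .riskpaf import RISK_FACTORS
from .upod import MortalitySurface

__all__ = [
    "NoiseConfig",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticBundle",
    "make_ground_truth",
    "generate_registry",
    "generate_surveys",
    "generate_rr_table",
    "generate_covariates",
    "generate_all",
]

# log mortality rate at (reference year 2015, age 50, both sexes) and
# per-year log-linear slope, per cause; calibrated so the 2015 national
# four-category 40q30 is ~0.14 and declines ~2%/yr
MORTALITY_ALPHA: dict[str, float] = {
    "cancers": -7.5033,
    "CVDs": -6.4042,
    "asthma_COPD": -8.2696,
    "diabetes_mellitus": -9.1904,
    "other": -7.0477,
}
MORTALITY_SLOPE: dict[str, float] = {
    "cancers": -0.050,
    "CVDs": -0.030,
    "asthma_COPD": -0.025,
    "diabetes_mellitus": -0.030,
    "other": -0.020,
}
AGE_LOG_SLOPE = 0.08          # per year of age, anchored at age 50
SEX_LOG_EFFECT = {"female": -0.08, "male": 0.08}
REFERENCE_YEAR = 2015

# national exposure anchors (2010 value, 2015 value) per sex; prevalences
# follow logistic trends through the anchors, means linear trends
EXPOSURE_ANCHORS: dict[str, dict[str, tuple[float, float]]] = {
    "diabetes": {"female": (0.089, 0.095), "male": (0.073, 0.079)},
    "blood_pressure": {"female": (129.0, 131.5), "male": (127.0, 129.5)},
    "bmi": {"female": (26.8, 27.4), "male": (25.2, 25.8)},
    "inactivity": {"female": (0.504, 0.586), "male": (0.385, 0.468)},
    "smoking": {"female": (0.037, 0.033), "male": (0.271, 0.243)},
    "salt": {"female": (9.6, 9.3), "male": (10.4, 9.9)},
}

# synthetic relative risks: categorical at-exposure RR or per-unit RR
# above the TMREL midpoint, per admissible pair
BASE_RR: dict[tuple[str, str], float] = {
    ("smoking", "cancers"): 2.2,
    ("smoking", "CVDs"): 1.8,
    ("smoking", "asthma_COPD"): 2.5,
    ("smoking", "diabetes_mellitus"): 1.3,
    ("diabetes", "CVDs"): 1.8,
    ("diabetes", "diabetes_mellitus"): 4.0,
    ("inactivity", "cancers"): 1.2,
    ("inactivity", "CVDs"): 1.4,
    ("inactivity", "diabetes_mellitus"): 1.5,
    ("blood_pressure", "CVDs"): 1.025,
    ("blood_pressure", "asthma_COPD"): 1.005,
    ("bmi", "cancers"): 1.03,
    ("bmi", "CVDs"): 1.06,
    ("bmi", "diabetes_mellitus"): 1.10,
    ("salt", "cancers"): 1.05,
    ("salt", "CVDs"): 1.03,
    ("salt", "asthma_COPD"): 1.01,
}

COVARIATE_POLY: dict[str, tuple[float, ...]] = {
    # value = c0 + c1 * t + c2 * t^2, t = year - 2001
    "wealth_index": (0.40, 0.012, 0.0002),
    "schooling_years": (6.5, 0.12, 0.0),
    "urbanization_pct": (58.0, 0.60, 0.0),
}

TOTAL_POPULATION_30_70 = 35_000_000.0
POPULATION_GROWTH = 0.012     # per year
AGE_POP_SLOPE = -0.05         # log population per year of age


@dataclass(frozen=True)
class NoiseConfig:
    """Toggles and magnitudes for stochastic components."""

    deaths: bool = True             # Poisson noise on registry counts
    surveys: bool = True            # binomial / normal sampling noise
    survey_sample_size: int = 2000  # per (round, sex, province)
    covariate_sd: float = 0.0       # additive noise on covariate trends


@dataclass(frozen=True)
class SimulationConfig:
    n_provinces: int = 31
    years_observed: tuple[int, int] = (2001, 2015)
    horizon_year: int = 2030
    age_bands: tuple[tuple[int, int], ...] = AGE_BANDS_30_70
    causes: tuple[str, ...] = ALL_CAUSES
    risks: tuple[str, ...] = RISKS
    survey_years: tuple[int, ...] = (2005, 2009, 2011, 2016)
    mortality_alpha: dict[str, float] = field(default_factory=lambda: dict(MORTALITY_ALPHA))
    mortality_slope: dict[str, float] = field(default_factory=lambda: dict(MORTALITY_SLOPE))
    exposure_anchors: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {r: dict(v) for r, v in EXPOSURE_ANCHORS.items()})
    province_effect_sd: float = 0.10
    exposure_province_sd: float = 0.08
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_provinces < 1:
            raise ValueError("n_provinces must be positive")
        if self.years_observed[0] > self.years_observed[1]:
            raise ValueError("years_observed must be an increasing range")
        if self.horizon_year <= self.years_observed[1]:
            raise ValueError("horizon_year must follow the observed range")
        los = [b[0] for b in self.age_bands]
        his = [b[1] for b in self.age_bands]
        if any(h <= l for l, h in self.age_bands) or his[:-1] != los[1:]:
            raise ValueError("age bands must be ordered, contiguous and non-overlapping")
        unknown = set(self.risks) - set(RISK_FACTORS)
        if unknown:
            raise ValueError(f"unknown risks {sorted(unknown)}")

    @property
    def years(self) -> range:
        return range(self.years_observed[0], self.years_observed[1] + 1)

    @property
    def provinces(self) -> range:
        return range(1, self.n_provinces + 1)


@dataclass(frozen=True)
class GroundTruth:
    """Deterministic generator internals, for parameter-recovery tests."""

    province_mortality_effect: np.ndarray      # (n_provinces,)
    province_exposure_effect: dict[str, np.ndarray]
    province_pop_weight: np.ndarray

    def mortality_rate(self, config: SimulationConfig, year, sex: str, province: int,
                       cause: str, age_mid) -> np.ndarray:
        """True death rate for a stratum (vectorised over year / age_mid)."""
        year = np.asarray(year, dtype=float)
        age_mid = np.asarray(age_mid, dtype=float)
        log_rate = (config.mortality_alpha[cause]
                    + config.mortality_slope[cause] * (year - REFERENCE_YEAR)
                    + AGE_LOG_SLOPE * (age_mid - 50.0)
                    + SEX_LOG_EFFECT[sex]
                    + self.province_mortality_effect[province - 1])
        return np.exp(log_rate)

    def exposure_value(self, config: SimulationConfig, risk: str, year, sex: str,
                       province: int | None = None) -> np.ndarray:
        """True exposure level (prevalence or mean) for a stratum."""
        year = np.asarray(year, dtype=float)
        v10, v15 = config.exposure_anchors[risk][sex]
        offset = 0.0 if province is None else self.province_exposure_effect[risk][province - 1]
        if RISK_FACTORS[risk].exposure_kind == METRIC_PREVALENCE:
            slope = (logit(v15) - logit(v10)) / 5.0
            return expit(logit(v15) + slope * (year - REFERENCE_YEAR) + offset)
        slope = (v15 - v10) / 5.0
        scale = RISK_FACTORS[risk].dist_sd
        return v15 + slope * (year - REFERENCE_YEAR) + offset * scale

    def population(self, config: SimulationConfig, year, sex: str, province: int,
                   age_mid) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        age_mid = np.asarray(age_mid, dtype=float)
        age_w = np.exp(AGE_POP_SLOPE * (age_mid - config.age_bands[0][0] - 2.5))
        age_w = age_w / np.sum(np.exp(
            AGE_POP_SLOPE * (np.array([b[0] + 2.5 for b in config.age_bands])
                             - config.age_bands[0][0] - 2.5)))
        total = TOTAL_POPULATION_30_70 * np.exp(POPULATION_GROWTH * (year - REFERENCE_YEAR))
        return total * self.province_pop_weight[province - 1] * 0.5 * age_w


@dataclass(frozen=True)
class SyntheticBundle:
    registry: MortalitySurface
    exposures: pd.DataFrame
    rr: pd.DataFrame
    covariates: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _structural_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 101])


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the deterministic structural effects implied by (config, seed)."""
    rng = _structural_rng(config)
    mort = rng.normal(0.0, config.province_effect_sd, config.n_provinces)
    mort -= mort.mean()
    expo = {}
    for risk in RISKS:  # fixed label order keeps draws stable across risk subsets
        e = rng.normal(0.0, config.exposure_province_sd, config.n_provinces)
        e -= e.mean()
        expo[risk] = e
    raw = np.exp(rng.normal(0.0, 0.6, config.n_provinces))
    return GroundTruth(
        province_mortality_effect=mort,
        province_exposure_effect=expo,
        province_pop_weight=raw / raw.sum(),
    )


def generate_registry(config: SimulationConfig, truth: GroundTruth | None = None) -> MortalitySurface:
    """Registry-style death counts and person-years, 2001-2015 by default.

    Counts are Poisson around population x true rate (or the rounded
    expectation when count noise is disabled).
    """
    truth = truth or make_ground_truth(config)
    rng = np.random.default_rng([config.seed, 202])
    years = np.array(list(config.years))
    rows = []
    for sex in SEXES:
        for province in config.provinces:
            for lo, hi in config.age_bands:
                mid = lo + (hi - lo) / 2.0
                pop = truth.population(config, years, sex, province, mid)
                for cause in config.causes:
                    rate = truth.mortality_rate(config, years, sex, province, cause, mid)
                    expected = pop * rate
                    if config.noise.deaths:
                        deaths = rng.poisson(expected)
                    else:
                        deaths = np.round(expected).astype(int)
                    rows.append(pd.DataFrame({
                        "year": years, "sex": sex, "province": province, "cause": cause,
                        "age_lo": lo, "age_hi": hi, "deaths": deaths,
                        "population": pop,
                    }))
    data = pd.concat(rows, ignore_index=True)[list(REGISTRY_COLUMNS)]
    return MortalitySurface(data)


def generate_surveys(config: SimulationConfig, truth: GroundTruth | None = None) -> pd.DataFrame:
    """Sparse survey rounds of exposure levels with sampling noise.

    Prevalence-type risks are drawn binomial / n around logistic trends,
    mean-type risks normal around linear trends; non-survey years are
    simply absent from the output.
    """
    truth = truth or make_ground_truth(config)
    rng = np.random.default_rng([config.seed, 303])
    n = config.noise.survey_sample_size
    rows = []
    for risk in config.risks:
        spec = RISK_FACTORS[risk]
        for sex in SEXES:
            for province in config.provinces:
                true = truth.exposure_value(config, risk, np.array(config.survey_years),
                                            sex, province)
                if spec.exposure_kind == METRIC_PREVALENCE:
                    se = np.sqrt(np.clip(true * (1 - true), 1e-12, None) / n)
                    value = rng.binomial(n, true) / n if config.noise.surveys else true
                else:
                    se = np.full_like(true, spec.dist_sd / np.sqrt(n))
                    value = rng.normal(true, se) if config.noise.surveys else true
                rows.append(pd.DataFrame({
                    "year": list(config.survey_years), "sex": sex, "province": province,
                    "risk": risk, "metric": spec.metric, "value": value, "se": se,
                }))
    return pd.concat(rows, ignore_index=True)[list(EXPOSURE_COLUMNS)]


def generate_rr_table(config: SimulationConfig, pairs=None) -> pd.DataFrame:
    """Synthetic relative risks per (risk, cause, sex, age band).

    RRs equal 1 at the TMREL by construction and carry a mild age gradient
    (log-RR attenuates with age) and sex contrast.
    """
    if pairs is None:
        pairs = [(r, c) for r, c in BASE_RR if r in config.risks]
    for r, c in pairs:
        if c not in ALLOWED_RISK_CAUSE.get(r, frozenset()):
            raise ValueError(f"inadmissible risk-cause pair ({r}, {c})")
        if (r, c) not in BASE_RR:
            raise ValueError(f"no base RR defined for pair ({r}, {c})")
    bands = config.age_bands
    n_bands = len(bands)
    age_factor = np.linspace(1.2, 0.8, n_bands)
    rows = []
    for risk, cause in pairs:
        kind = RR_CATEGORICAL if RISK_FACTORS[risk].exposure_kind == METRIC_PREVALENCE else RR_PER_UNIT
        log_rr = np.log(BASE_RR[(risk, cause)])
        for sex, sex_factor in (("female", 0.95), ("male", 1.05)):
            rr = np.exp(log_rr * age_factor * sex_factor)
            for (lo, hi), val in zip(bands, rr):
                rows.append({"risk": risk, "cause": cause, "sex": sex,
                             "age_lo": lo, "age_hi": hi, "kind": kind,
                             "rr": float(val)})
    return pd.DataFrame(rows)


def generate_covariates(config: SimulationConfig, truth: GroundTruth | None = None) -> pd.DataFrame:
    """Smooth monotone covariate trends per province through the horizon.

    Produces wealth index, years of schooling, urbanization (clamped to
    [0, 100]) and total province population for every year from the start
    of observation to the horizon year.
    """
    truth = truth or make_ground_truth(config)
    rng = np.random.default_rng([config.seed, 404])
    years = np.arange(config.years_observed[0], config.horizon_year + 1)
    t = years - config.years_observed[0]
    age_mids = np.array([b[0] + (b[1] - b[0]) / 2.0 for b in config.age_bands])
    rows = []
    for province in config.provinces:
        shift = truth.province_pop_weight[province - 1] / truth.province_pop_weight.mean()
        for cov, (c0, c1, c2) in COVARIATE_POLY.items():
            base = c0 * (0.8 + 0.2 * shift) + c1 * t + c2 * t**2
            if config.noise.covariate_sd > 0:
                base = base + rng.normal(0.0, config.noise.covariate_sd, base.size)
            if cov == "urbanization_pct":
                base = np.clip(base, 0.0, 100.0)
            rows.append(pd.DataFrame({"year": years, "province": province,
                                      "covariate": cov, "value": base}))
        pop = np.zeros(years.size)
        for sex in SEXES:
            for mid in age_mids:
                pop = pop + truth.population(config, years, sex, province, mid)
        rows.append(pd.DataFrame({"year": years, "province": province,
                                  "covariate": "population", "value": pop}))
    return pd.concat(rows, ignore_index=True)[list(COVARIATE_COLUMNS)]


def generate_all(config: SimulationConfig) -> SyntheticBundle:
    """Generate the complete input bundle with a shared ground truth."""
    truth = make_ground_truth(config)
    return SyntheticBundle(
        registry=generate_registry(config, truth),
        exposures=generate_surveys(config, truth),
        rr=generate_rr_table(config),
        covariates=generate_covariates(config, truth),
        truth=truth,
        config=config,
    )
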