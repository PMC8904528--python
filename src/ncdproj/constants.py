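"""Label sets and coding conventions shared across the package.

All tables are long-format CSV with a header row, UTF-8, half-open age
intervals ``[age_lo, age_hi)``, sex coded ``{female, male, both}`` and
provinces coded by integer id.
"""

from __future__ import annotations

CAUSES_NCD4: tuple[str, ...] = ("cancers", "CVDs", "asthma_COPD", "diabetes_mellitus")
CAUSE_OTHER: str = "other"
ALL_CAUSES: tuple[str, ...] = CAUSES_NCD4 + (CAUSE_OTHER,)

SEXES: tuple[str, ...] = ("female", "male")
SEX_BOTH: str = "both"

#: eight 5-year bands covering exact ages 30-70
AGE_BANDS_30_70: tuple[tuple[int, int], ...] = tuple((lo, lo + 5) for lo in range(30, 70, 5))

RISKS: tuple[str, ...] = (
    "blood_pressure",
    "diabetes",
    "bmi",
    "inactivity",
    "smoking",
    "salt",
)

#: admissible risk -> cause pairings (coarse NCD categories)
ALLOWED_RISK_CAUSE: dict[str, frozenset[str]] = {
    "blood_pressure": frozenset({"CVDs", "asthma_COPD"}),
    "diabetes": frozenset({"CVDs", "diabetes_mellitus"}),
    "bmi": frozenset({"cancers", "CVDs", "diabetes_mellitus"}),
    "inactivity": frozenset({"cancers", "CVDs", "diabetes_mellitus"}),
    "smoking": frozenset({"cancers", "CVDs", "asthma_COPD", "diabetes_mellitus"}),
    "salt": frozenset({"cancers", "CVDs", "asthma_COPD"}),
}

REGISTRY_COLUMNS = ("year", "sex", "province", "cause", "age_lo", "age_hi", "deaths", "population")
EXPOSURE_COLUMNS = ("year", "sex", "province", "risk", "metric", "value", "se")
RR_COLUMNS = ("risk", "cause", "sex", "age_lo", "age_hi", "kind", "rr")
COVARIATE_COLUMNS = ("year", "province", "covariate", "value")

METRIC_PREVALENCE = "prevalence"
METRIC_MEAN = "mean"

RR_CATEGORICAL = "categorical"
RR_PER_UNIT = "per_unit"
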