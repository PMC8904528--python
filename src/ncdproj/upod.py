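"""Unconditional probability of dying between exact ages 30 and 70 (40q30).

The indicator is built from age-band-specific mortality rates (5mx) via the
standard conversion to conditional death probabilities (5qx) assuming deaths
occur mid-interval, then chained over the eight 5-year bands::

    40q30 = 1 - prod_x (1 - 5qx)

Cause-specific values use the cause's own rates in the same formula, i.e.
the cause is treated as if acting alone (no competing-risk adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AGE_BANDS_30_70, CAUSES_NCD4, REGISTRY_COLUMNS, SEX_BOTH

__all__ = [
    "MortalitySurface",
    "UPoDResult",
    "age_specific_rate",
    "prob_from_rate",
    "upod_30_70",
    "upod_from_rates",
    "upod_table",
    "upod_uncertainty",
]


@dataclass
class MortalitySurface:
    """Death counts and person-years in long format.

    ``data`` carries one row per (year, sex, province, cause, age band)
    with both the cause-specific death count and the stratum population
    (the population column repeats across causes within a stratum).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REGISTRY_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"registry table missing columns {sorted(missing)}")
        if (self.data["deaths"] < 0).any():
            raise ValueError("death counts must be non-negative")
        if (self.data["population"] <= 0).any():
            bad = self.data.loc[self.data["population"] <= 0,
                                ["year", "sex", "province", "age_lo"]].iloc[0]
            raise ValueError(f"non-positive population in stratum {tuple(bad)}")

    def rates(self, causes=None, sex=None, province=None, year=None) -> pd.DataFrame:
        """Pooled age-specific rates 5mx.

        Deaths are summed over the requested causes and over any stratifier
        left as ``None`` (pooling deaths and person-years before dividing,
        never averaging ratios).  Returns a frame with columns
        (year?, sex?, province?, age_lo, age_hi, deaths, population, mx).
        """
        df = self.data
        if causes is not None:
            df = df[df["cause"].isin(list(causes))]
        if sex is not None and sex != SEX_BOTH:
            df = df[df["sex"] == sex]
        if province is not None:
            df = df[df["province"] == province]
        if year is not None:
            df = df[df["year"] == year]
        if df.empty:
            raise ValueError("no registry rows match the requested stratum")
        keys = ["age_lo", "age_hi"]
        if year is None:
            keys = ["year"] + keys
        deaths = df.groupby(keys, as_index=False)["deaths"].sum()
        # population rows repeat per cause: take one cause's rows
        pop_src = df[df["cause"] == df["cause"].iloc[0]]
        pop = pop_src.groupby(keys, as_index=False)["population"].sum()
        out = deaths.merge(pop, on=keys)
        out["mx"] = out["deaths"] / out["population"]
        return out


@dataclass(frozen=True)
class UPoDResult:
    value: float
    ui_low: float
    ui_high: float
    stratum: dict

    def __post_init__(self) -> None:
        if not (0 <= self.ui_low <= self.value <= self.ui_high <= 1):
            raise ValueError("require 0 <= ui_low <= value <= ui_high <= 1")


def age_specific_rate(deaths, population):
    """5mx = deaths / person-years; vectorised."""
    deaths = np.asarray(deaths, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        idx = int(np.argmax(np.atleast_1d(population <= 0)))
        raise ValueError(f"population must be positive (offending index {idx})")
    if np.any(deaths < 0):
        raise ValueError("deaths must be non-negative")
    out = deaths / population
    return float(out) if out.ndim == 0 else out


def prob_from_rate(m, width: float = 5.0):
    """Convert a rate 5mx to the conditional probability 5qx.

    ``5qx = width * m / (1 + (width / 2) * m)`` (mid-interval deaths),
    capped at 1.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("mortality rate must be non-negative")
    q = width * m / (1.0 + (width / 2.0) * m)
    q = np.minimum(q, 1.0)
    return float(q) if q.ndim == 0 else q


def upod_30_70(rates, age_lo=None) -> float:
    """40q30 from the eight age-band rates [30,35) ... [65,70).

    ``rates`` is an 8-vector ordered by age unless ``age_lo`` labels are
    given, in which case completeness is checked against the expected
    bands.
    """
    rates = np.asarray(rates, dtype=float)
    if age_lo is not None:
        expected = [lo for lo, _ in AGE_BANDS_30_70]
        present = list(np.asarray(age_lo, dtype=int))
        missing = sorted(set(expected) - set(present))
        if missing:
            raise ValueError(f"missing age bands starting at {missing}")
        order = np.argsort(present)
        rates = rates[order][np.searchsorted(np.sort(present), expected)]
    if rates.shape != (len(AGE_BANDS_30_70),):
        raise ValueError(f"expected {len(AGE_BANDS_30_70)} age-band rates, got {rates.shape}")
    q = prob_from_rate(rates)
    return float(1.0 - np.prod(1.0 - q))


def upod_from_rates(rates_df: pd.DataFrame) -> float:
    """40q30 from a rates frame as produced by :meth:`MortalitySurface.rates`."""
    return upod_30_70(rates_df["mx"].to_numpy(), age_lo=rates_df["age_lo"].to_numpy())


def upod_table(surface: MortalitySurface, causes=CAUSES_NCD4, by=("year", "sex")) -> pd.DataFrame:
    """Point-estimate UPoD for every stratum combination in ``by``.

    ``by`` may contain "year", "sex", "province"; omitted dimensions are
    pooled.  Returns long-format rows with a ``upod`` column.
    """
    df = surface.data[surface.data["cause"].isin(list(causes))]
    pop_src = surface.data[surface.data["cause"] == surface.data["cause"].iloc[0]]
    keys = [k for k in ("year", "sex", "province") if k in by]
    gcols = keys + ["age_lo", "age_hi"]
    deaths = df.groupby(gcols, as_index=False)["deaths"].sum()
    pop = pop_src.groupby(gcols, as_index=False)["population"].sum()
    merged = deaths.merge(pop, on=gcols)
    merged["mx"] = merged["deaths"] / merged["population"]
    rows = []
    for key, grp in merged.groupby(keys) if keys else [((), merged)]:
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(keys, key)) | {"upod": upod_from_rates(grp)})
    return pd.DataFrame(rows)


def upod_uncertainty(surface: MortalitySurface, draws: int = 1000, seed: int = 0,
                     causes=CAUSES_NCD4, sex=None, province=None, year=None) -> UPoDResult:
    """Parametric-bootstrap 95% uncertainty interval for one stratum.

    Deaths are resampled as Poisson around the observed counts, UPoD is
    recomputed per draw and the interval taken at the 2.5/97.5 percentiles.
    """
    if draws < 100:
        raise ValueError("need at least 100 bootstrap draws")
    rates = surface.rates(causes=causes, sex=sex, province=province, year=year)
    if "year" in rates.columns:
        agg = rates.groupby(["age_lo", "age_hi"], as_index=False)[["deaths", "population"]].sum()
    else:
        agg = rates
    deaths = agg["deaths"].to_numpy(dtype=float)
    pop = agg["population"].to_numpy(dtype=float)
    age_lo = agg["age_lo"].to_numpy()
    point = upod_30_70(deaths / pop, age_lo=age_lo)
    rng = np.random.default_rng(seed)
    sim_deaths = rng.poisson(deaths, size=(draws, deaths.size))
    sim = np.array([upod_30_70(d / pop, age_lo=age_lo) for d in sim_deaths])
    lo, hi = np.percentile(sim, [2.5, 97.5])
    stratum = {"year": year, "sex": sex or SEX_BOTH, "province": province,
               "causes": tuple(causes)}
    return UPoDResult(value=point, ui_low=float(min(lo, point)),
                      ui_high=float(max(hi, point)), stratum=stratum)
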