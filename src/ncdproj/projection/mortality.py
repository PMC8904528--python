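"""Log-linear mortality-rate trends per stratum with province shrinkage.

Each (sex, cause, province, age band) series gets an ordinary
least-squares trend on log((deaths + 0.5) / population); province slopes
are shrunk toward the national (pooled-deaths) slope for the same
(sex, cause, age band) with weight ``w = n_years / (n_years + tau)``.
Population person-years are extrapolated the same way on the log scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..upod import MortalitySurface

logger = logging.getLogger(__name__)

__all__ = ["project_mortality", "project_population"]

_MIN_YEARS = 8


def _ols_by_group(df: pd.DataFrame, keys: list[str], ycol: str) -> pd.DataFrame:
    """Per-group slope/intercept of ycol on year (intercept at mean year)."""
    g = df.groupby(keys)
    out = g.agg(n=("year", "size"), mean_x=("year", "mean"), mean_y=(ycol, "mean")).reset_index()
    tmp = df.merge(out, on=keys)
    tmp["dx"] = tmp["year"] - tmp["mean_x"]
    tmp["dy"] = tmp[ycol] - tmp["mean_y"]
    tmp["dxdy"] = tmp["dx"] * tmp["dy"]
    tmp["dx2"] = tmp["dx"] ** 2
    s = tmp.groupby(keys)[["dxdy", "dx2"]].sum().reset_index()
    out = out.merge(s, on=keys)
    out["slope"] = np.where(out["dx2"] > 0, out["dxdy"] / out["dx2"], 0.0)
    return out[keys + ["n", "mean_x", "mean_y", "slope"]]


def project_mortality(surface: MortalitySurface, horizon_year: int,
                      tau: float = 5.0) -> pd.DataFrame:
    """Projected death rates per (year, sex, cause, province, age band).

    Returns every year from the first observed year to ``horizon_year``
    with columns (..., mx, provenance); provenance is ``fitted`` within the
    observed range and ``projected`` beyond.  Strata with no deaths in any
    observed year are projected as zero with a logged warning.
    """
    df = surface.data.copy()
    n_years = df["year"].nunique()
    if n_years < _MIN_YEARS:
        raise ValueError(f"need at least {_MIN_YEARS} observed years, got {n_years}")
    last_obs = int(df["year"].max())
    df["lograte"] = np.log((df["deaths"] + 0.5) / df["population"])

    keys = ["sex", "cause", "province", "age_lo", "age_hi"]
    prov_fit = _ols_by_group(df, keys, "lograte")

    nat = df.groupby(["sex", "cause", "age_lo", "age_hi", "year"], as_index=False)[
        ["deaths", "population"]].sum()
    nat["lograte"] = np.log((nat["deaths"] + 0.5) / nat["population"])
    nat_fit = _ols_by_group(nat, ["sex", "cause", "age_lo", "age_hi"], "lograte")
    nat_fit = nat_fit.rename(columns={"slope": "nat_slope"})[
        ["sex", "cause", "age_lo", "age_hi", "nat_slope"]]

    fit = prov_fit.merge(nat_fit, on=["sex", "cause", "age_lo", "age_hi"])
    w = fit["n"] / (fit["n"] + tau)
    fit["slope_shrunk"] = w * fit["slope"] + (1 - w) * fit["nat_slope"]

    zero = df.groupby(keys)["deaths"].sum().reset_index(name="total_deaths")
    fit = fit.merge(zero, on=keys)
    n_zero = int((fit["total_deaths"] == 0).sum())
    if n_zero:
        logger.warning("%d strata with zero deaths across all years projected as rate 0", n_zero)

    years = np.arange(int(df["year"].min()), horizon_year + 1)
    rep = fit.loc[fit.index.repeat(years.size)].reset_index(drop=True)
    rep["year"] = np.tile(years, len(fit))
    rep["mx"] = np.exp(rep["mean_y"] + rep["slope_shrunk"] * (rep["year"] - rep["mean_x"]))
    rep.loc[rep["total_deaths"] == 0, "mx"] = 0.0
    rep["provenance"] = np.where(rep["year"] <= last_obs, "fitted", "projected")
    return rep[["year"] + keys + ["mx", "provenance"]]


def project_population(surface: MortalitySurface, horizon_year: int) -> pd.DataFrame:
    """Log-linear extrapolation of person-years per (sex, province, age band)."""
    df = surface.data
    pop = df[df["cause"] == df["cause"].iloc[0]][
        ["year", "sex", "province", "age_lo", "age_hi", "population"]].copy()
    pop["logpop"] = np.log(pop["population"])
    keys = ["sex", "province", "age_lo", "age_hi"]
    fit = _ols_by_group(pop, keys, "logpop")
    years = np.arange(int(pop["year"].min()), horizon_year + 1)
    rep = fit.loc[fit.index.repeat(years.size)].reset_index(drop=True)
    rep["year"] = np.tile(years, len(fit))
    rep["population"] = np.exp(rep["mean_y"] + rep["slope"] * (rep["year"] - rep["mean_x"]))
    return rep[["year"] + keys + ["population"]]
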