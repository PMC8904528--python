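"""Dense series from sparse survey rounds, GP smoothing, spline covariates.

The spatiotemporal model is deliberately simple: each province's observed
rounds are honoured exactly, gaps are filled by piecewise-linear
interpolation on a transformed scale (logit for prevalences), and
extrapolation beyond the observed rounds blends the province's own edge
slope with the national edge slope using a shrinkage weight
``w = n_rounds / (n_rounds + tau)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.special import expit, logit
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from ..constants import METRIC_PREVALENCE

__all__ = ["spatiotemporal_interpolate", "gpr_smooth", "spline_extrapolate", "spline_curve"]


def _edge_slopes(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    first = (y[1] - y[0]) / (x[1] - x[0])
    last = (y[-1] - y[-2]) / (x[-1] - x[-2])
    return first, last


def _fill(years: np.ndarray, obs_x: np.ndarray, obs_y: np.ndarray,
          slope_lo: float, slope_hi: float) -> np.ndarray:
    out = np.interp(years, obs_x, obs_y)
    before = years < obs_x[0]
    after = years > obs_x[-1]
    out[before] = obs_y[0] + slope_lo * (years[before] - obs_x[0])
    out[after] = obs_y[-1] + slope_hi * (years[after] - obs_x[-1])
    return out


def spatiotemporal_interpolate(sparse: pd.DataFrame, year_start: int, year_end: int,
                               tau: float = 2.0) -> pd.DataFrame:
    """Fill every year in ``[year_start, year_end]`` for each stratum.

    ``sparse`` is an exposure table (year, sex, province, risk, metric,
    value[, se]).  Observed rounds are reproduced exactly; interior years
    are linearly interpolated on the working scale; years outside the
    observed rounds use the shrinkage-blended edge slope, which covers both
    back-casting before the first round and projection past the last.
    Requires at least two observed rounds per (risk, sex, province).
    """
    years = np.arange(year_start, year_end + 1)
    out_rows = []
    for (risk, sex), grp in sparse.groupby(["risk", "sex"], sort=True):
        metric = grp["metric"].iloc[0]
        to_work = (lambda v: logit(np.clip(v, 1e-9, 1 - 1e-9))) \
            if metric == METRIC_PREVALENCE else (lambda v: v)
        from_work = expit if metric == METRIC_PREVALENCE else (lambda v: v)

        nat = grp.groupby("year")["value"].mean()
        if len(nat) < 2:
            raise ValueError(f"cannot interpolate ({risk}, {sex}): fewer than two rounds")
        nat_x = nat.index.to_numpy(dtype=float)
        nat_y = to_work(nat.to_numpy(dtype=float))
        nat_lo, nat_hi = _edge_slopes(nat_x, nat_y)

        for province, pgrp in grp.groupby("province", sort=True):
            pgrp = pgrp.sort_values("year")
            obs_x = pgrp["year"].to_numpy(dtype=float)
            if obs_x.size < 2:
                raise ValueError(
                    f"cannot interpolate ({risk}, {sex}, province {province}): single round")
            obs_y = to_work(pgrp["value"].to_numpy(dtype=float))
            w = obs_x.size / (obs_x.size + tau)
            p_lo, p_hi = _edge_slopes(obs_x, obs_y)
            filled = _fill(years, obs_x, obs_y,
                           w * p_lo + (1 - w) * nat_lo,
                           w * p_hi + (1 - w) * nat_hi)
            values = from_work(filled)
            observed_map = dict(zip(obs_x.astype(int), pgrp["value"].to_numpy(dtype=float)))
            prov = np.where(np.isin(years, obs_x.astype(int)), "observed",
                            np.where((years < obs_x[0]) | (years > obs_x[-1]),
                                     "projected", "interpolated"))
            values = np.array([observed_map.get(int(yv), v)
                               for yv, v in zip(years, values)])
            out_rows.append(pd.DataFrame({
                "year": years, "sex": sex, "province": province, "risk": risk,
                "metric": metric, "value": values, "provenance": prov,
            }))
    return pd.concat(out_rows, ignore_index=True)


def gpr_smooth(series: pd.DataFrame, amplitude: float = 1.0, length_scale: float = 5.0,
               noise_sd: float = 0.01, year_col: str = "year",
               value_col: str = "value") -> pd.DataFrame:
    """Gaussian-process posterior over one time series.

    Squared-exponential kernel with fixed hyperparameters (no marginal
    likelihood optimisation, for reproducibility); prior mean is the data
    mean, so the smoother reverts there far from observations.  Returns a
    frame with columns (year, value, ui_low, ui_high).
    """
    if amplitude <= 0 or length_scale <= 0:
        raise ValueError("amplitude and length_scale must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if len(series) < 3:
        raise ValueError("need at least 3 points to smooth")
    x = series[year_col].to_numpy(dtype=float).reshape(-1, 1)
    y = series[value_col].to_numpy(dtype=float)
    kernel = ConstantKernel(amplitude ** 2, "fixed") * RBF(length_scale, "fixed")
    gp = GaussianProcessRegressor(kernel=kernel, alpha=max(noise_sd ** 2, 1e-12),
                                  optimizer=None, normalize_y=True)
    gp.fit(x, y)
    mean, sd = gp.predict(x, return_std=True)
    return pd.DataFrame({
        year_col: series[year_col].to_numpy(),
        value_col: mean,
        "ui_low": mean - 1.959963984540054 * sd,
        "ui_high": mean + 1.959963984540054 * sd,
    })


def spline_curve(x: np.ndarray, y: np.ndarray, x_new: np.ndarray) -> np.ndarray:
    """Natural cubic spline through (x, y) with linear tail extrapolation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observed points for spline extrapolation")
    cs = CubicSpline(x, y, bc_type="natural")
    x_new = np.asarray(x_new, dtype=float)
    out = cs(x_new)
    lo_slope = float(cs(x[0], 1))
    hi_slope = float(cs(x[-1], 1))
    below = x_new < x[0]
    above = x_new > x[-1]
    out[below] = y[0] + lo_slope * (x_new[below] - x[0])
    out[above] = y[-1] + hi_slope * (x_new[above] - x[-1])
    return out


def spline_extrapolate(covariates: pd.DataFrame, horizon_year: int) -> pd.DataFrame:
    """Extend covariate series (year, province, covariate, value) to the horizon.

    Natural cubic spline over the observed years per (province, covariate),
    linear beyond the last knot; urbanization percentages are clamped to
    [0, 100].
    """
    rows = []
    for (province, cov), grp in covariates.groupby(["province", "covariate"], sort=True):
        grp = grp.sort_values("year")
        obs_x = grp["year"].to_numpy(dtype=float)
        years = np.arange(int(obs_x[0]), horizon_year + 1)
        vals = spline_curve(obs_x, grp["value"].to_numpy(dtype=float), years)
        if cov == "urbanization_pct":
            vals = np.clip(vals, 0.0, 100.0)
        prov = np.where(np.isin(years, obs_x.astype(int)), "observed", "projected")
        rows.append(pd.DataFrame({"year": years, "province": province,
                                  "covariate": cov, "value": vals, "provenance": prov}))
    return pd.concat(rows, ignore_index=True)
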