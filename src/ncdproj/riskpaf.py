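"""Population attributable fractions (PAF) and potential impact fractions (PIF).

Per-risk fractions are computed within (age, sex, cause, province, year)
cells and combined across risks multiplicatively::

    joint PAF = 1 - prod_i (1 - PAF_i)

Categorical exposures use the Levin form; continuous exposures compare the
observed normal exposure distribution against a uniform distribution on the
theoretical-minimum (TMREL) interval under a log-linear per-unit relative
risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ALLOWED_RISK_CAUSE, METRIC_MEAN, METRIC_PREVALENCE, RR_COLUMNS

__all__ = [
    "RiskFactorSpec",
    "RISK_FACTORS",
    "paf_categorical",
    "paf_continuous",
    "pif",
    "pif_continuous",
    "joint_paf",
    "validate_rr_table",
]


@dataclass(frozen=True)
class RiskFactorSpec:
    """Static description of one modifiable risk factor.

    Parameters
    ----------
    name : str
        Canonical risk label.
    exposure_kind : {"prevalence", "continuous-mean"}
        Whether the exposure metric is a population prevalence in [0, 1]
        or a population mean on a physical scale.
    units : str
        Unit of the exposure metric.
    tmrel : tuple of float
        Theoretical-minimum risk exposure interval ``(low, high)``.
    related_causes : frozenset of str
        Admissible cause categories for this risk.
    dist_sd : float
        Population standard deviation assumed for continuous exposures
        (used when integrating the exposure distribution).
    """

    name: str
    exposure_kind: str
    units: str
    tmrel: tuple[float, float]
    related_causes: frozenset[str]
    dist_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.exposure_kind not in (METRIC_PREVALENCE, "continuous-mean"):
            raise ValueError(f"unknown exposure kind {self.exposure_kind!r}")
        if self.tmrel[0] > self.tmrel[1]:
            raise ValueError("tmrel_low must be <= tmrel_high")

    @property
    def tmrel_mid(self) -> float:
        return 0.5 * (self.tmrel[0] + self.tmrel[1])

    @property
    def metric(self) -> str:
        return METRIC_PREVALENCE if self.exposure_kind == METRIC_PREVALENCE else METRIC_MEAN


RISK_FACTORS: dict[str, RiskFactorSpec] = {
    s.name: s
    for s in (
        RiskFactorSpec("blood_pressure", "continuous-mean", "mmHg", (110.0, 115.0),
                       ALLOWED_RISK_CAUSE["blood_pressure"], dist_sd=15.0),
        RiskFactorSpec("diabetes", "prevalence", "proportion", (0.0, 0.0),
                       ALLOWED_RISK_CAUSE["diabetes"]),
        RiskFactorSpec("bmi", "continuous-mean", "kg/m^2", (21.0, 25.0),
                       ALLOWED_RISK_CAUSE["bmi"], dist_sd=4.5),
        RiskFactorSpec("inactivity", "prevalence", "proportion", (0.0, 0.0),
                       ALLOWED_RISK_CAUSE["inactivity"]),
        RiskFactorSpec("smoking", "prevalence", "proportion", (0.0, 0.0),
                       ALLOWED_RISK_CAUSE["smoking"]),
        RiskFactorSpec("salt", "continuous-mean", "g/day", (1.0, 5.0),
                       ALLOWED_RISK_CAUSE["salt"], dist_sd=3.0),
    )
}

#: grid resolution for numerical integration of continuous exposures
_GRID_POINTS = 2001
_GRID_HALF_WIDTH_SD = 6.0


def paf_categorical(p, rr):
    """Levin attributable fraction for a prevalence exposure.

    ``PAF = p (rr - 1) / (p (rr - 1) + 1)``; vectorised over inputs.
    """
    p = np.asarray(p, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prevalence must lie in [0, 1]")
    if np.any(rr <= 0):
        raise ValueError("relative risk must be positive")
    excess = p * (rr - 1.0)
    out = excess / (excess + 1.0)
    return float(out) if out.ndim == 0 else out


def pif(p_observed, p_counterfactual, rr):
    """Potential impact fraction for a prevalence shift ``p -> p*``.

    ``PIF = (p - p*)(rr - 1) / (p (rr - 1) + 1)``.  Reduces to
    :func:`paf_categorical` when the counterfactual prevalence is zero and
    to 0 when nothing changes.
    """
    p = np.asarray(p_observed, dtype=float)
    ps = np.asarray(p_counterfactual, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any((ps < 0) | (ps > 1)):
        raise ValueError("prevalences must lie in [0, 1]")
    if np.any(rr <= 0):
        raise ValueError("relative risk must be positive")
    out = (p - ps) * (rr - 1.0) / (p * (rr - 1.0) + 1.0)
    return float(out) if out.ndim == 0 else out


def relative_risk_at(x, rr_per_unit: float, tmrel_mid: float):
    """Log-linear dose-response: ``RR(x) = rr_per_unit ** max(0, x - tmrel_mid)``.

    Equals 1 at (or below) the TMREL midpoint by construction.
    """
    return np.power(rr_per_unit, np.maximum(0.0, np.asarray(x, dtype=float) - tmrel_mid))


_rr_curve = relative_risk_at


def _mean_rr(mean: float, sd: float, spec: RiskFactorSpec, rr_per_unit: float,
             grid: int) -> float:
    """E[RR(X)] for X ~ Normal(mean, sd), trapezoid rule on mean +/- 6 sd."""
    x = np.linspace(mean - _GRID_HALF_WIDTH_SD * sd, mean + _GRID_HALF_WIDTH_SD * sd, grid)
    f = np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    val = np.trapezoid(_rr_curve(x, rr_per_unit, spec.tmrel_mid) * f, x)
    if not np.isfinite(val):
        raise ValueError("divergent exposure integral; rr_per_unit too large for grid")
    return float(val)


def paf_continuous(mean: float, sd: float, spec: RiskFactorSpec, rr_per_unit: float,
                   grid: int = _GRID_POINTS) -> float:
    """Attributable fraction for a continuous-mean exposure.

    ``PAF = (E_f[RR] - 1) / E_f[RR]`` with ``f = Normal(mean, sd)`` and
    ``RR(x) = rr_per_unit ** max(0, x - tmrel_mid)``: the TMREL
    counterfactual distribution carries no excess risk (RR = 1) by
    definition, so its expected relative risk is exactly 1.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if rr_per_unit <= 0:
        raise ValueError("rr_per_unit must be positive")
    observed = _mean_rr(mean, sd, spec, rr_per_unit, grid)
    return (observed - 1.0) / observed


def pif_continuous(mean_observed: float, mean_counterfactual: float, sd: float,
                   spec: RiskFactorSpec, rr_per_unit: float,
                   grid: int = _GRID_POINTS) -> float:
    """Impact fraction for shifting a continuous exposure mean."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if rr_per_unit <= 0:
        raise ValueError("rr_per_unit must be positive")
    observed = _mean_rr(mean_observed, sd, spec, rr_per_unit, grid)
    shifted = _mean_rr(mean_counterfactual, sd, spec, rr_per_unit, grid)
    return (observed - shifted) / observed


def joint_paf(pafs) -> float:
    """Multiplicative combination ``1 - prod(1 - PAF_i)`` across risks."""
    arr = np.asarray(list(pafs), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one PAF")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("each PAF must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - arr))


def validate_rr_table(rr: pd.DataFrame) -> pd.DataFrame:
    """Check an RR table against the admissible risk-cause pairings.

    Returns the table unchanged; raises ``ValueError`` naming offending
    rows otherwise.
    """
    missing = set(RR_COLUMNS) - set(rr.columns)
    if missing:
        raise ValueError(f"RR table missing columns {sorted(missing)}")
    if (rr["rr"] <= 0).any():
        raise ValueError("all relative risks must be positive")
    bad = [
        (row.risk, row.cause)
        for row in rr[["risk", "cause"]].drop_duplicates().itertuples()
        if row.cause not in ALLOWED_RISK_CAUSE.get(row.risk, frozenset())
    ]
    if bad:
        raise ValueError(f"inadmissible risk-cause pairs: {sorted(set(bad))}")
    return rr
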