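"""Abridged life tables, temporary life expectancy and cause deletion.

Conventions: radix 100 000, mid-interval deaths (a_x = width / 2) for
closed bands, L = l / m for an open-ended final band.  Cause deletion uses
the associated-single-decrement form p* = p ** (1 - R) (Chiang), with the
proportional-rate alternative m * (1 - R) available via ``method``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .upod import prob_from_rate

__all__ = [
    "LifeTable",
    "build_life_table",
    "temporary_life_expectancy",
    "cause_deleted_table",
]

RADIX = 100_000.0


@dataclass
class LifeTable:
    """Abridged life table with one row per age band.

    Columns: age_lo, age_hi, width, mx, qx, lx, dx, Lx, Tx, ex.  An
    infinite ``age_hi`` marks an open-ended final band.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (np.diff(t["lx"].to_numpy()) > 1e-9).any():
            raise ValueError("survivorship lx must be non-increasing")
        if ((t["qx"] < 0) | (t["qx"] > 1)).any():
            raise ValueError("qx must lie in [0, 1]")

    @property
    def closes(self) -> bool:
        return bool(np.isinf(self.table["age_hi"].iloc[-1]) or self.table["qx"].iloc[-1] == 1.0)


def _assemble(age_lo: np.ndarray, age_hi: np.ndarray, mx: np.ndarray,
              qx: np.ndarray) -> LifeTable:
    width = np.where(np.isinf(age_hi), np.nan, age_hi - age_lo)
    n = len(qx)
    lx = np.empty(n)
    lx[0] = RADIX
    for i in range(n - 1):
        lx[i + 1] = lx[i] * (1.0 - qx[i])
    dx = lx * qx
    Lx = np.empty(n)
    for i in range(n):
        if np.isinf(age_hi[i]):
            Lx[i] = lx[i] / mx[i] if mx[i] > 0 else 0.0
        else:
            survivors = lx[i] - dx[i]
            Lx[i] = width[i] * survivors + (width[i] / 2.0) * dx[i]
    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    return LifeTable(pd.DataFrame({
        "age_lo": age_lo, "age_hi": age_hi, "width": width, "mx": mx, "qx": qx,
        "lx": lx, "dx": dx, "Lx": Lx, "Tx": Tx, "ex": ex,
    }))


def build_life_table(rates: pd.DataFrame) -> LifeTable:
    """Build an abridged table from (age_lo, age_hi, mx) rows.

    Bands must be ordered and contiguous; an infinite final ``age_hi``
    closes the table with q = 1 and L = l / m.
    """
    rates = rates.sort_values("age_lo").reset_index(drop=True)
    age_lo = rates["age_lo"].to_numpy(dtype=float)
    age_hi = rates["age_hi"].to_numpy(dtype=float)
    mx = rates["mx"].to_numpy(dtype=float)
    if np.any(mx < 0):
        raise ValueError("mortality rates must be non-negative")
    if not np.allclose(age_lo[1:], age_hi[:-1]):
        raise ValueError("age bands must be contiguous")
    qx = np.empty_like(mx)
    for i in range(len(mx)):
        if np.isinf(age_hi[i]):
            qx[i] = 1.0
        else:
            qx[i] = prob_from_rate(mx[i], width=age_hi[i] - age_lo[i])
    return _assemble(age_lo, age_hi, mx, qx)


def temporary_life_expectancy(table: LifeTable, age_from: float = 30.0,
                              age_to: float = 70.0) -> float:
    """Expected years lived between two exact ages, e(from -> to).

    ``(T(from) - T(to)) / l(from)``; bounded above by the window width.
    """
    t = table.table
    sel = (t["age_lo"] >= age_from) & (t["age_hi"] <= age_to)
    covered = t.loc[sel, ["age_lo", "age_hi"]]
    if covered.empty or covered["age_lo"].iloc[0] != age_from or covered["age_hi"].iloc[-1] != age_to:
        raise ValueError(f"table does not cover [{age_from}, {age_to})")
    l_from = t.loc[t["age_lo"] == age_from, "lx"].iloc[0]
    if l_from <= 0:
        raise ValueError("no survivors at the window start")
    return float(t.loc[sel, "Lx"].sum() / l_from)


def cause_deleted_table(table: LifeTable, profile, method: str = "chiang") -> LifeTable:
    """Rebuild the table with one cause's mortality removed.

    ``profile`` gives R, the fraction of deaths from the deleted cause per
    age band (array-like aligned with the table, or a frame with columns
    age_lo, R).  ``method`` selects the associated-single-decrement form
    ``p* = p ** (1 - R)`` ("chiang") or the proportional rate
    ``m* = m (1 - R)`` ("proportional").
    """
    t = table.table
    if isinstance(profile, pd.DataFrame):
        r = t[["age_lo"]].merge(profile[["age_lo", "R"]], on="age_lo", how="left")["R"].to_numpy()
        if np.isnan(r).any():
            raise ValueError("profile missing age bands present in the table")
    else:
        r = np.asarray(profile, dtype=float)
        if r.shape != (len(t),):
            raise ValueError("profile length must match the table")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("cause fractions R must lie in [0, 1]")
    qx = t["qx"].to_numpy()
    mx = t["mx"].to_numpy()
    if method == "chiang":
        px_star = np.power(1.0 - qx, 1.0 - r)
        # r = 0 must leave q bit-identical, and deletion can never raise q
        qx_star = np.where(r == 0.0, qx, np.minimum(1.0 - px_star, qx))
        # implied rate consistent with the new q (for open-band L)
        mx_star = mx * (1.0 - r)
    elif method == "proportional":
        mx_star = mx * (1.0 - r)
        width = t["age_hi"].to_numpy() - t["age_lo"].to_numpy()
        qx_star = np.where(np.isinf(t["age_hi"].to_numpy()), 1.0,
                           prob_from_rate(mx_star, width=np.where(np.isfinite(width), width, 5.0)))
    else:
        raise ValueError(f"unknown deletion method {method!r}")
    qx_star = np.where(np.isinf(t["age_hi"].to_numpy()), 1.0, qx_star)
    return _assemble(t["age_lo"].to_numpy(), t["age_hi"].to_numpy(), mx_star, qx_star)
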