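"""CSV dialects, configuration loading and input validation.

All tables are long-format UTF-8 CSV with a header row; age intervals are
half-open ``[age_lo, age_hi)``; missing data is an empty field.  Floats are
written with ``repr`` round-tripping so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .constants import (
    ALLOWED_RISK_CAUSE,
    EXPOSURE_COLUMNS,
    METRIC_PREVALENCE,
    REGISTRY_COLUMNS,
    RR_COLUMNS,
)
from .upod import MortalitySurface

__all__ = [
    "read_registry",
    "read_exposures",
    "read_rr",
    "read_covariates",
    "write_table",
    "load_yaml_config",
    "validate_inputs",
    "ValidationReport",
]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table deterministically (stable row order, full float repr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=None, lineterminator="\n")
    return path


def read_registry(path: str | Path) -> MortalitySurface:
    df = pd.read_csv(path)
    return MortalitySurface(df[list(REGISTRY_COLUMNS)])


def read_exposures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EXPOSURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"exposure table missing columns {sorted(missing)}")
    return df


def read_rr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"RR table missing columns {sorted(missing)}")
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=repr).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.issues.append(msg)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        return "ok" if self.ok else "\n".join(self.issues)


def _check_age_contiguity(df: pd.DataFrame, report: ValidationReport, label: str) -> None:
    for key, grp in df.groupby(["year", "sex", "province"]):
        bands = grp[["age_lo", "age_hi"]].drop_duplicates().sort_values("age_lo")
        lo = bands["age_lo"].to_numpy()
        hi = bands["age_hi"].to_numpy()
        if (hi <= lo).any() or (lo[1:] != hi[:-1]).any():
            report.add(f"{label}: non-contiguous age bands in stratum {key}")


def validate_inputs(tables: dict) -> ValidationReport:
    """Structural validation of an input bundle.

    ``tables`` maps any of {"registry", "exposures", "rr"} to data frames;
    issues are returned, not raised, so callers can enumerate all problems
    at once.
    """
    report = ValidationReport()
    reg = tables.get("registry")
    if reg is not None:
        df = reg.data if isinstance(reg, MortalitySurface) else reg
        missing = set(REGISTRY_COLUMNS) - set(df.columns)
        if missing:
            report.add(f"registry: missing columns {sorted(missing)}")
        else:
            for idx in df.index[df["deaths"] < 0]:
                report.add(f"registry: negative deaths at row {idx}")
            for idx in df.index[df["population"] <= 0]:
                report.add(f"registry: non-positive population at row {idx}")
            _check_age_contiguity(df, report, "registry")
    exp = tables.get("exposures")
    if exp is not None:
        prev = exp[exp["metric"] == METRIC_PREVALENCE]
        bad = prev.index[(prev["value"] < 0) | (prev["value"] > 1)]
        for idx in bad:
            report.add(f"exposures: prevalence outside [0, 1] at row {idx}")
    rr = tables.get("rr")
    if rr is not None:
        for idx in rr.index[rr["rr"] <= 0]:
            report.add(f"rr: non-positive relative risk at row {idx}")
        for row in rr[["risk", "cause"]].drop_duplicates().itertuples():
            if row.cause not in ALLOWED_RISK_CAUSE.get(row.risk, frozenset()):
                report.add(f"rr: inadmissible risk-cause pair ({row.risk}, {row.cause})")
    return report
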