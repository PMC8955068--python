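"""CSV readers/writers for design tables and concentration profiles.

Design tables are comma-separated with a header row; one row per
formulation run with factor settings in actual units and measured
responses.  Profile tables have columns time, concentration, tissue
(brain|blood), route (IV|IN) and group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig
from .errors import DataError, FormatError, ParseError
from .nca import ConcentrationProfile

__all__ = [
    "RunRecord",
    "read_design_table",
    "write_design_table",
    "read_profile_table",
    "write_profile_table",
]

log = logging.getLogger(__name__)


@dataclass
class RunRecord:
    """One formulation run: factor settings (actual units) and responses."""

    run: str
    factors: dict[str, float]
    responses: dict[str, float]

    def __post_init__(self) -> None:
        ps = self.responses.get("PS")
        if ps is not None and ps <= 0:
            raise DataError(f"run {self.run}: particle size must be positive")
        for name in ("EE", "CDR"):
            v = self.responses.get(name)
            if v is not None and not 0 <= v <= 100:
                raise DataError(f"run {self.run}: {name} must lie in [0, 100]")


def _require_columns(df: pd.DataFrame, names, path) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {out[col].iloc[row]!r} "
                f"in column {col!r} at data row {row}"
            )
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise ParseError(f"{path}: empty cell in column {col!r} at data row {row}")
        out[col] = parsed
    return out


def read_design_table(path: str | Path, config: StudyConfig) -> list[RunRecord]:
    """Read a design/response table; one RunRecord per row, order preserved."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    needed = list(config.factor_names) + list(config.response_names)
    _require_columns(df, needed, path)
    if df.empty:
        return []
    df = _numeric(df, needed, path)
    labels = (df["run"].astype(str) if "run" in df.columns
              else pd.Series([f"R{i + 1}" for i in range(len(df))]))
    records = []
    for i in range(len(df)):
        records.append(RunRecord(
            run=str(labels.iloc[i]),
            factors={n: float(df[n].iloc[i]) for n in config.factor_names},
            responses={n: float(df[n].iloc[i]) for n in config.response_names},
        ))
    return records


def write_design_table(records: list[RunRecord], path: str | Path) -> None:
    rows = [{"run": r.run, **r.factors, **r.responses} for r in records]
    # shortest round-trippable decimal form of each float
    pd.DataFrame(rows).to_csv(path, index=False,
                              float_format=lambda v: repr(float(v)))


PROFILE_COLUMNS = ("time", "concentration", "tissue", "route", "group")


def read_profile_table(path: str | Path) -> list[ConcentrationProfile]:
    """Read concentration-time profiles, one per (tissue, route, group).

    Times within a profile must be unique; unsorted rows are sorted with
    a warning.  Negative concentrations are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PROFILE_COLUMNS, path)
    if df.empty:
        return []
    df = _numeric(df, ("time", "concentration"), path)
    profiles = []
    for (tissue, route, group), g in df.groupby(
            ["tissue", "route", "group"], sort=False):
        t = g["time"].to_numpy(dtype=float)
        c = g["concentration"].to_numpy(dtype=float)
        if np.unique(t).size != t.size:
            raise DataError(
                f"{path}: duplicate time in profile ({tissue}, {route}, {group})"
            )
        if np.any(c < 0):
            raise DataError(
                f"{path}: negative concentration in profile ({tissue}, {route}, {group})"
            )
        if np.any(np.diff(t) < 0):
            log.warning("profile (%s, %s, %s) has unsorted times; sorting",
                        tissue, route, group)
            order = np.argsort(t)
            t, c = t[order], c[order]
        profiles.append(ConcentrationProfile(
            tissue=str(tissue), route=str(route), group=str(group),
            times_min=t, concentrations_ng_ml=c,
        ))
    return profiles


def write_profile_table(profiles: list[ConcentrationProfile],
                        path: str | Path) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times_min, p.concentrations_ng_ml):
            rows.append({"time": t, "concentration": c, "tissue": p.tissue,
                         "route": p.route, "group": p.group})
    pd.DataFrame(rows, columns=list(PROFILE_COLUMNS)).to_csv(
        path, index=False, float_format=lambda v: repr(float(v)))
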