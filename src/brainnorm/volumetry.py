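"""Volume-table I/O, head-size normalization and the log transform.

Column contract for volume tables (CSV):

    subject_id, scan_id, scan_ordinal, age, sex, site, protocol_id,
    slice_resolution_mm, total_volume_mm3, vol_<structure>...

``vol_`` columns are raw structure volumes in mm^3; ``total_volume_mm3`` is
the total intracranial volume (brain + sulci + cranial space, themselves
present as ``vol_brain``, ``vol_sulci``, ``vol_cranial_space``).  Extra
columns (e.g. the generator's ``latent_*`` diagnostics) are preserved.

Two head-size corrections are provided: the proportional method (volume
divided by total volume, giving a dimensionless fraction carried internally;
percentages appear only at report boundaries) and the residuals method

    Vol_adj = Vol - b * (TotalVol - TotalVol_mean)

with b the OLS slope of Vol on TotalVol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "read_volume_table",
    "write_volume_table",
    "validate_volume_table",
    "structure_columns",
    "proportional_normalize",
    "ResidualAdjustModel",
    "fit_residual_model",
    "residual_adjust",
    "log_transform",
    "select_first_scan",
    "decade_of",
]

REQUIRED_COLUMNS = (
    "subject_id",
    "scan_id",
    "scan_ordinal",
    "age",
    "sex",
    "site",
    "protocol_id",
    "slice_resolution_mm",
    "total_volume_mm3",
)

VOLUME_PREFIX = "vol_"


def structure_columns(table: pd.DataFrame) -> list[str]:
    """All raw-volume columns (``vol_*``), compartments included."""
    return [c for c in table.columns if c.startswith(VOLUME_PREFIX)]


def validate_volume_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"volume table is missing required columns: {missing}")
    if not structure_columns(table):
        raise ValueError("volume table has no 'vol_<structure>' columns")
    vol_cols = structure_columns(table) + ["total_volume_mm3"]
    for col in vol_cols:
        bad = table.index[~(table[col] > 0)]
        if len(bad):
            ident = table.loc[bad[0], ["subject_id", "scan_id"]].tolist()
            raise ValueError(
                f"non-positive volume in column {col!r} at row {bad[0]} "
                f"(subject_id={ident[0]!r}, scan_id={ident[1]!r})"
            )
    dup = table.duplicated(subset=["subject_id", "scan_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject_id, scan_id) pair at row {int(np.flatnonzero(dup)[0])}"
        )
    return table


def read_volume_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"subject_id": str, "scan_id": str})
    return validate_volume_table(table)


def write_volume_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_volume_table(table)
    table.to_csv(path, index=False)


def _volume_column(table: pd.DataFrame, structure: str) -> str:
    col = structure if structure in table.columns else VOLUME_PREFIX + structure
    if col not in table.columns:
        raise KeyError(f"structure column {structure!r} not found in table")
    return col


def proportional_normalize(table: pd.DataFrame, structure: str) -> pd.Series:
    """Relative volume: raw structure volume / total volume (fraction)."""
    col = _volume_column(table, structure)
    total = table["total_volume_mm3"]
    if (total <= 0).any():
        raise ValueError("total_volume_mm3 must be positive")
    return table[col] / total


@dataclass(frozen=True)
class ResidualAdjustModel:
    """Residuals-method head-size correction for one structure."""

    structure: str
    b: float
    total_volume_mean: float

    def __post_init__(self) -> None:
        if self.total_volume_mean <= 0:
            raise ValueError("total_volume_mean must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ResidualAdjustModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_residual_model(table: pd.DataFrame, structure: str) -> ResidualAdjustModel:
    col = _volume_column(table, structure)
    if len(table) < 3:
        raise ValueError("need at least 3 rows to fit the residual model")
    total = table["total_volume_mm3"].to_numpy(float)
    if np.ptp(total) == 0:
        raise ValueError("total volume is constant; residual slope is undefined")
    vol = table[col].to_numpy(float)
    b = float(np.polyfit(total, vol, 1)[0])
    return ResidualAdjustModel(
        structure=structure.removeprefix(VOLUME_PREFIX),
        b=b,
        total_volume_mean=float(total.mean()),
    )


def residual_adjust(table: pd.DataFrame, model: ResidualAdjustModel) -> pd.Series:
    """Vol_adj = Vol - b * (TotalVol - TotalVol_mean), in mm^3."""
    col = _volume_column(table, model.structure)
    return table[col] - model.b * (table["total_volume_mm3"] - model.total_volume_mean)


def log_transform(fractions) -> np.ndarray | pd.Series:
    """Natural log of relative volumes (homoscedasticity transform)."""
    arr = np.asarray(fractions, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("log transform requires strictly positive values")
    out = np.log(arr)
    if isinstance(fractions, pd.Series):
        return pd.Series(out, index=fractions.index, name=fractions.name)
    return out


def select_first_scan(table: pd.DataFrame) -> pd.DataFrame:
    """Keep the minimal-ordinal scan for each subject."""
    if "scan_ordinal" not in table.columns:
        raise ValueError("table lacks the scan_ordinal column")
    dup = table.duplicated(subset=["subject_id", "scan_ordinal"])
    if dup.any():
        subj = table.loc[np.flatnonzero(dup)[0], "subject_id"]
        raise ValueError(f"duplicate scan_ordinal for subject {subj!r}")
    idx = table.groupby("subject_id", sort=False)["scan_ordinal"].idxmin()
    return table.loc[idx.sort_values().sort_index()].sort_index().reset_index(drop=True)


def decade_of(ages) -> pd.Series:
    """Decade bin of an age in years (20s..90s as the decade's start)."""
    ages = pd.Series(ages)
    dec = (np.floor(ages / 10.0) * 10).astype(int)
    return dec.clip(lower=20, upper=90)
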