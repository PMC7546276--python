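"""NONMEM-style tabular dataset reader/writer and validation.

A study dataset is a long-format table with one row per dose event or
observation:

======  =====================================================================
ID      subject identifier (integer)
OCC     occasion label (string; here, the study each record belongs to)
TIME    hours since the first dose of the occasion
AMT     dose amount in µg (0 for observation rows)
ROUTE   ``iv`` or ``oral`` on dose rows, empty (``.``) on observation rows
DV      observed concentration in ng/ml (``.`` on dose rows)
MDV     1 when DV is missing (dose rows), else 0
BLQ     1 when the observation is below the quantification limit; DV then
        holds the censoring bound (the LLOQ), not a measurement
LLOQ    lower limit of quantification, ng/ml
WT0     bodyweight, kg
SEX     categorical covariate
FED     feeding status covariate
======  =====================================================================

Each occasion carries its own clock (time restarts at the first dose of the
occasion), consistent with complete washout between studies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StudyDataset", "read_dataset", "write_dataset", "DatasetFormatError"]

COLUMNS = [
    "ID", "OCC", "TIME", "AMT", "ROUTE", "DV", "MDV", "BLQ", "LLOQ",
    "WT0", "SEX", "FED",
]

NUMERIC = ["TIME", "AMT", "DV", "MDV", "BLQ", "LLOQ", "WT0"]


class DatasetFormatError(ValueError):
    """The file does not conform to the expected tabular layout."""


@dataclass
class StudyDataset:
    """A validated longitudinal PK dataset (dose events + observations)."""

    df: pd.DataFrame
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise DatasetFormatError(f"missing mandatory columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)

    @property
    def subjects(self) -> list:
        return sorted(self.df["ID"].unique().tolist())

    def occasions(self, subject) -> list:
        sub = self.df[self.df["ID"] == subject]
        return list(dict.fromkeys(sub["OCC"].tolist()))

    @property
    def n_observations(self) -> int:
        return int((self.df["MDV"] == 0).sum())

    def covariates(self) -> pd.DataFrame:
        """One row per subject: WT0, SEX, FED."""
        return (
            self.df.groupby("ID")[["WT0", "SEX", "FED"]]
            .first()
            .reset_index()
            .sort_values("ID")
            .reset_index(drop=True)
        )

    def validate(self) -> list:
        """Check dataset invariants; returns human-readable warnings.

        Hard violations (non-numeric fields, missing columns) raise; soft
        rule violations are reported with the offending row numbers.
        """
        warnings = []
        df = self.df
        for col in NUMERIC:
            vals = pd.to_numeric(df[col].replace(".", np.nan), errors="coerce")
            present = df[col].notna() & df[col].astype(str).str.strip().ne(".")
            bad = df.index[present & vals.isna()]
            if len(bad):
                raise DatasetFormatError(
                    f"non-numeric values in column {col} at rows {list(bad)}"
                )
        time = pd.to_numeric(df["TIME"], errors="coerce")
        if (time < 0).any():
            warnings.append(
                f"negative TIME at rows {list(df.index[time < 0])}"
            )
        for (sid, occ), grp in df.groupby(["ID", "OCC"], sort=False):
            t = pd.to_numeric(grp["TIME"], errors="coerce").to_numpy()
            if np.any(np.diff(t) < 0):
                warnings.append(f"TIME not sorted for subject {sid} occasion {occ}")
        for sid, grp in df.groupby("ID"):
            amt = pd.to_numeric(grp["AMT"], errors="coerce").fillna(0)
            mdv = pd.to_numeric(grp["MDV"], errors="coerce").fillna(1)
            if not (amt > 0).any():
                warnings.append(f"subject {sid} has no dose row")
            if not (mdv == 0).any():
                warnings.append(f"subject {sid} has no observation row")
        obs = df[pd.to_numeric(df["MDV"], errors="coerce") == 0]
        dv = pd.to_numeric(obs["DV"], errors="coerce")
        lloq = pd.to_numeric(obs["LLOQ"], errors="coerce")
        blq = pd.to_numeric(obs["BLQ"], errors="coerce")
        bad_blq = obs.index[(dv < lloq) & (blq == 0)]
        if len(bad_blq):
            warnings.append(
                f"DV below LLOQ but BLQ flag not set at rows {list(bad_blq)}"
            )
        bad_bound = obs.index[(blq == 1) & (dv != lloq)]
        if len(bad_bound):
            warnings.append(
                f"BLQ rows where DV is not the LLOQ bound at rows {list(bad_bound)}"
            )
        wt = pd.to_numeric(df["WT0"], errors="coerce")
        if (wt <= 0).any():
            warnings.append(f"non-positive WT0 at rows {list(df.index[wt <= 0])}")
        self.warnings = warnings
        return warnings


_HEADER_COMMENT = (
    "# vitacoxib population-PK dataset\n"
    "# units: TIME h, AMT ug, DV ng/ml, LLOQ ng/ml, WT0 kg\n"
)


def read_dataset(path) -> StudyDataset:
    """Read a comma- or tab-delimited dataset file and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    sep = "\t" if "\t" in lines[0] else ","
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep=sep, dtype=str)
    df.columns = [c.strip().upper() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing mandatory columns: {missing}")
    for col in NUMERIC:
        converted = pd.to_numeric(df[col].replace(".", np.nan), errors="coerce")
        notdot = df[col].astype(str).str.strip().ne(".")
        bad = df.index[notdot & converted.isna()]
        if len(bad):
            raise DatasetFormatError(
                f"non-numeric values in column {col} at rows {list(bad)}"
            )
        df[col] = converted
    df["ID"] = pd.to_numeric(df["ID"], errors="coerce").astype(int)
    ds = StudyDataset(df)
    ds.validate()
    return ds


def write_dataset(ds: StudyDataset, path) -> None:
    """Write the canonical tabular form: fixed column order, '.' for missing."""
    df = ds.df.copy()
    for col in ["AMT", "TIME", "LLOQ", "WT0"]:
        df[col] = df[col].map(lambda v: _fmt(v))
    df["DV"] = df["DV"].map(lambda v: "." if pd.isna(v) else _fmt(v))
    df["ROUTE"] = df["ROUTE"].fillna(".").replace("", ".")
    for col in ["MDV", "BLQ"]:
        df[col] = df[col].astype(float).astype(int)
    out = _HEADER_COMMENT + df.to_csv(index=False)
    Path(path).write_text(out)


def _fmt(v) -> str:
    if pd.isna(v):
        return "."
    f = float(v)
    return f"{f:.6g}"
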