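"""NONMEM-style dataset reading, writing and validation.

Column dialect: ID, TIME, AMT, RATE, EVID, CMT, DV, MDV, WT, FED, ROUTE,
STUDY.  EVID 0 rows are observations (DV in mg/L, AMT empty); EVID 1 rows are
doses (AMT > 0 mg, MDV 1, RATE > 0 marks a zero-order infusion of duration
AMT/RATE).  CMT is 1 for the oral depot and 2 for central.  Time is hours
from each subject's first event; no date handling.  "." or an empty field is
the missing-value token on read; empty is written.

Observations recorded at a dose time are treated as pre-dose (trough) samples
regardless of row order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DatasetError
from .params import IV, PO, DoseEvent

REQUIRED_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "CMT", "DV", "MDV",
    "WT", "FED", "ROUTE", "STUDY",
]

CMT_DEPOT = 1
CMT_CENTRAL = 2


@dataclass(frozen=True)
class SubjectRecord:
    """Parsed per-subject view: doses, observation times and values."""

    id: object
    wt: float
    study: str
    doses: tuple[DoseEvent, ...]
    obs_times: np.ndarray  # MDV == 0 observations only
    dv: np.ndarray


@dataclass
class PKDataset:
    """A validated longitudinal PK dataset wrapping a pandas DataFrame."""

    df: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        """Number of usable PK samples (EVID 0, MDV 0)."""
        return int(((self.df["EVID"] == 0) & (self.df["MDV"] == 0)).sum())

    def subjects(self) -> Iterator[SubjectRecord]:
        for sid, g in self.df.groupby("ID", sort=False):
            doses = []
            for _, row in g[g["EVID"] == 1].iterrows():
                route = row["ROUTE"]
                amt = float(row["AMT"])
                rate = float(row["RATE"]) if np.isfinite(row["RATE"]) else 0.0
                dur = amt / rate if rate > 0 else 0.0
                fed = bool(int(row["FED"])) if route == PO else None
                doses.append(DoseEvent(float(row["TIME"]), amt, route, dur, fed))
            obs = g[(g["EVID"] == 0) & (g["MDV"] == 0)]
            yield SubjectRecord(
                id=sid,
                wt=float(g["WT"].iloc[0]),
                study=str(g["STUDY"].iloc[0]),
                doses=tuple(doses),
                obs_times=obs["TIME"].to_numpy(dtype=float),
                dv=obs["DV"].to_numpy(dtype=float),
            )


def validate(df: pd.DataFrame) -> list[str]:
    """All invariant violations, each message carrying the offending row number.

    Row numbers are 1-based data rows (header excluded), matching what a user
    sees in the CSV.
    """
    errors: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing required column(s): {', '.join(missing)}"]

    def rownum(idx) -> int:
        return int(idx) + 1

    for idx, row in df.iterrows():
        evid = row["EVID"]
        if evid not in (0, 1):
            errors.append(f"row {rownum(idx)}: EVID must be 0 or 1, got {evid!r}")
            continue
        if not np.isfinite(row["TIME"]) or row["TIME"] < 0:
            errors.append(f"row {rownum(idx)}: TIME must be a non-negative number")
        if evid == 0:
            if not np.isfinite(row["DV"]):
                errors.append(f"row {rownum(idx)}: observation row has no DV")
            if np.isfinite(row["AMT"]) and row["AMT"] != 0:
                errors.append(f"row {rownum(idx)}: observation row must not carry AMT")
            if row["MDV"] not in (0, 1):
                errors.append(f"row {rownum(idx)}: MDV must be 0 or 1")
        else:
            if not (np.isfinite(row["AMT"]) and row["AMT"] > 0):
                errors.append(f"row {rownum(idx)}: dose row requires AMT > 0")
            if row["MDV"] != 1:
                errors.append(f"row {rownum(idx)}: dose row requires MDV = 1")
            if np.isfinite(row["DV"]):
                errors.append(f"row {rownum(idx)}: dose row must not carry DV")
            if row["ROUTE"] not in (IV, PO):
                errors.append(f"row {rownum(idx)}: ROUTE must be IV or PO on dose rows")
            elif row["ROUTE"] == PO and row["FED"] not in (0, 1):
                errors.append(f"row {rownum(idx)}: PO dose row requires FED in {{0, 1}}")

    for sid, g in df.groupby("ID", sort=False):
        t = g["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            bad = g.index[1:][np.diff(t) < 0][0]
            errors.append(f"row {rownum(bad)}: TIME not sorted within ID {sid}")
        wt = g["WT"].to_numpy(dtype=float)
        if not np.all(np.isfinite(wt)) or wt.size == 0:
            errors.append(f"ID {sid}: WT missing")
        elif np.ptp(wt) != 0:
            errors.append(f"ID {sid}: WT must be constant within subject")
    return errors


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("TIME", "AMT", "RATE", "DV", "WT"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("EVID", "MDV"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    if "CMT" in df.columns:
        df["CMT"] = pd.to_numeric(df["CMT"], errors="coerce").astype("Int64")
    if "FED" in df.columns:
        df["FED"] = pd.to_numeric(df["FED"], errors="coerce")
    if "RATE" in df.columns:
        df["RATE"] = df["RATE"].fillna(0.0)
    return df


def read_dataset(path) -> PKDataset:
    """Read and validate a CSV dataset; the load is all-or-nothing."""
    df = pd.read_csv(path, na_values=["."], keep_default_na=True,
                     float_precision="round_trip")
    df = _coerce(df)
    errors = validate(df)
    if errors:
        raise DatasetError("dataset failed validation:\n" + "\n".join(errors))
    return PKDataset(df)


def write_dataset(ds: PKDataset, path) -> None:
    """Write the dataset as CSV with empty fields for missing values."""
    ds.df.to_csv(path, index=False, na_rep="")


def from_rows(rows: list[dict]) -> PKDataset:
    """Build a validated dataset from row dictionaries (generator back-end)."""
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    df = _coerce(df)
    errors = validate(df)
    if errors:
        raise DatasetError("generated dataset failed validation:\n" + "\n".join(errors))
    return PKDataset(df)
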