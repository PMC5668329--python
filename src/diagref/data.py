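"""Ingest, recode, filter and tabulate person-level mobility records.

Records live in a pandas DataFrame with columns

    origin, destination   education levels (low/medium/high)
    outcome               binary, 1 = overweight/obese (BMI >= 25 kg/m^2)
    age                   years; age_c is the mean-centred version
    marital_status        no_partner / married_cohab / unmarried_cohab / no_cohabitation
    native                1 = both parents born in the country
    weight                positive case weight (default 1)
    enrolled              1 = still in education (excluded from analysis)
    sex                   male / female (pipeline-level stratification)

Eligibility follows the survey protocol: adults only (age >= 18, so
self-reported BMI is a valid overweight screen), respondents still enrolled
in education excluded (their destination is not final), and listwise
deletion of records with missing origin, destination, outcome or covariates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .levels import LEVELS, MARITAL_LEVELS, RANK

REQUIRED_COLUMNS = ("origin", "destination", "outcome")
COVARIATE_COLUMNS = ("age", "marital_status", "native")


class DegenerateDataError(ValueError):
    """Raised when filtering leaves no usable records."""


@dataclass
class FilterReport:
    """Reconciliation of eligibility filtering: input = retained + removals."""

    n_input: int
    n_removed_age: int
    n_removed_enrolled: int
    n_removed_missing: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_removed_age + self.n_removed_enrolled + self.n_removed_missing
        if self.n_input != self.n_retained + removed:
            raise ValueError("filter report does not reconcile")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class MobilityTable:
    """Square origin x destination count table with margins.

    Counts are unweighted respondents (margins are derived, never stored
    inconsistently).  Immobile individuals sit on the diagonal, downwardly
    mobile below it, upwardly mobile above it.
    """

    counts: pd.DataFrame  # index = origin levels, columns = destination levels

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out["total"] = self.row_totals
        out.loc["total"] = list(self.col_totals) + [self.grand_total]
        out.to_csv(path, index_label="origin")


def compute_owob(height_cm, weight_kg) -> np.ndarray:
    """Overweight/obesity indicator: BMI = kg/m^2 >= 25."""
    h = np.asarray(height_cm, dtype=float) / 100.0
    bmi = np.asarray(weight_kg, dtype=float) / h**2
    return (bmi >= 25.0).astype(int)


def add_mobility_status(df: pd.DataFrame) -> pd.DataFrame:
    """Attach a mobility_status column (immobile/upward/downward)."""
    o = df["origin"].map(RANK)
    d = df["destination"].map(RANK)
    status = np.where(d > o, "upward", np.where(d < o, "downward", "immobile"))
    out = df.copy()
    out["mobility_status"] = status
    return out


def apply_eligibility_filters(
    df: pd.DataFrame,
    min_age: float = 18.0,
    exclude_enrolled: bool = True,
    required: tuple[str, ...] = REQUIRED_COLUMNS + COVARIATE_COLUMNS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the age / enrolment / missingness filters, in that order.

    Returns the retained records and a :class:`FilterReport` whose counts
    reconcile exactly.  Raises :class:`DegenerateDataError` if nothing
    survives.
    """
    n_input = len(df)
    work = df.copy()

    age_ok = pd.to_numeric(work["age"], errors="coerce") >= min_age
    n_removed_age = int((~age_ok.fillna(False)).sum()) if "age" in work else 0
    work = work[age_ok.fillna(False)]

    if exclude_enrolled and "enrolled" in work.columns:
        enrolled = work["enrolled"].fillna(0).astype(float) > 0
        n_removed_enrolled = int(enrolled.sum())
        work = work[~enrolled]
    else:
        n_removed_enrolled = 0

    present = [c for c in required if c in work.columns and c != "age"]
    complete = work[present].notna().all(axis=1)
    n_removed_missing = int((~complete).sum())
    work = work[complete]

    report = FilterReport(
        n_input=n_input,
        n_removed_age=n_removed_age,
        n_removed_enrolled=n_removed_enrolled,
        n_removed_missing=n_removed_missing,
        n_retained=len(work),
    )
    if report.n_retained == 0:
        raise DegenerateDataError("no records retained after eligibility filtering")
    return work.reset_index(drop=True), report


def tabulate(df: pd.DataFrame, levels: tuple[str, ...] = LEVELS) -> MobilityTable:
    """Unweighted origin x destination respondent counts with margins."""
    if len(df) == 0:
        raise DegenerateDataError("cannot tabulate an empty record set")
    counts = pd.crosstab(df["origin"], df["destination"])
    counts = counts.reindex(index=levels, columns=levels, fill_value=0)
    counts.index.name = "origin"
    counts.columns.name = "destination"
    return MobilityTable(counts=counts.astype(int))


def center_covariate(values, weights=None) -> tuple[np.ndarray, float]:
    """Centre a covariate around its (weighted) mean; returns (centred, mean)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot centre an empty sequence")
    if weights is None:
        mean = float(x.mean())
    else:
        w = np.asarray(weights, dtype=float)
        mean = float(np.average(x, weights=w))
    return x - mean, mean


def read_records(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a records CSV, optionally renaming columns via ``column_map``.

    If the file carries height_cm/weight_kg instead of a binary outcome,
    the overweight indicator is computed from BMI.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "outcome" not in df.columns:
        if {"height_cm", "weight_kg"} <= set(df.columns):
            df["outcome"] = compute_owob(df["height_cm"], df["weight_kg"])
        else:
            raise ValueError(f"{path}: need an 'outcome' column or height_cm + weight_kg")
    for col, default in (("weight", 1.0), ("enrolled", 0)):
        if col not in df.columns:
            df[col] = default
    return df


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def marital_dummies(df: pd.DataFrame) -> pd.DataFrame:
    """Marital-status dummies with no_partner as the reference category."""
    out = {}
    for lvl in MARITAL_LEVELS[1:]:
        out[lvl] = (df["marital_status"] == lvl).astype(float)
    return pd.DataFrame(out, index=df.index)
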