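"""Person-year ("long format") cohort records.

A cohort is stored as a pandas DataFrame with one row per individual per
observed year of follow-up.  Each row carries the state at the start of the
year (age, CCI, DCI) and the year's outcome: death, censoring, or the
next-year comorbidity values.

Columns
-------
person_id : int        opaque individual identifier
region    : int        health-care region label, 1..n_regions
year_index: int >= 0   years since cohort entry
age       : int        age at the start of the year, 65..105
cci       : int >= 0   Charlson Comorbidity Index (cumulative, never falls)
dci       : float      Drug Comorbidity Index, on a 0.25 grid from -0.75
died      : 0/1        death during this year
censored  : 0/1        follow-up ends this year without death
cci_next  : int or NaN next-year CCI; absent when died or censored
dci_next  : float/NaN  next-year DCI; absent when died or censored
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "COLUMNS",
    "AGE_MIN",
    "AGE_MAX",
    "DCI_FLOOR",
    "DCI_STEP",
    "PersonYearRecord",
    "validate_cohort",
    "on_dci_grid",
]

COLUMNS = (
    "person_id",
    "region",
    "year_index",
    "age",
    "cci",
    "dci",
    "died",
    "censored",
    "cci_next",
    "dci_next",
)

AGE_MIN = 65
AGE_MAX = 105
DCI_FLOOR = -0.75
DCI_STEP = 0.25


@dataclass
class PersonYearRecord:
    """One observation-year of one individual (row-level view of a cohort)."""

    person_id: int
    region: int
    year_index: int
    age: int
    cci: int
    dci: float
    died: int
    censored: int
    cci_next: Optional[int] = None
    dci_next: Optional[float] = None


def on_dci_grid(x, atol: float = 1e-9):
    """True where x lies on the DCI grid {-0.75 + 0.25 k, k >= 0}."""
    arr = np.asarray(x, dtype=float)
    k = (arr - DCI_FLOOR) / DCI_STEP
    return np.isclose(k, np.round(k), atol=atol) & (arr >= DCI_FLOOR - atol)


def _fail(mask: np.ndarray, df: pd.DataFrame, message: str) -> None:
    if mask.any():
        row = int(df.index[np.flatnonzero(mask)[0]])
        raise ValidationError(f"row {row}: {message}")


def validate_cohort(df: pd.DataFrame) -> None:
    """Check every person-year invariant; raise ValidationError naming a row.

    Row numbers in messages are the DataFrame index (the reader sets the
    index to the file line number).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    if len(df) == 0:
        return

    age = df["age"].to_numpy(dtype=float)
    cci = df["cci"].to_numpy(dtype=float)
    dci = df["dci"].to_numpy(dtype=float)
    died = df["died"].to_numpy(dtype=float)
    cens = df["censored"].to_numpy(dtype=float)
    cci_next = df["cci_next"].to_numpy(dtype=float)
    dci_next = df["dci_next"].to_numpy(dtype=float)

    _fail(~np.isin(died, (0, 1)), df, "died must be 0 or 1")
    _fail(~np.isin(cens, (0, 1)), df, "censored must be 0 or 1")
    _fail((died == 1) & (cens == 1), df, "died and censored cannot both be 1")
    _fail((age < AGE_MIN) | (age > AGE_MAX), df,
          f"age outside [{AGE_MIN}, {AGE_MAX}]")
    _fail(cci < 0, df, "cci must be >= 0")
    _fail(~on_dci_grid(dci), df,
          "dci must lie on the 0.25 grid starting at -0.75")

    ended = (died == 1) | (cens == 1)
    has_cn = ~np.isnan(cci_next)
    has_dn = ~np.isnan(dci_next)
    _fail(ended & (has_cn | has_dn), df,
          "cci_next/dci_next must be absent when died or censored")
    _fail(~ended & ~(has_cn & has_dn), df,
          "cci_next and dci_next required for a completed year")
    _fail(has_cn & (cci_next < cci), df,
          "cci_next < cci violates the cumulative-CCI invariant")
    _fail(has_dn & ~on_dci_grid(np.where(has_dn, dci_next, DCI_FLOOR)), df,
          "dci_next must lie on the 0.25 grid starting at -0.75")

    dup = df.duplicated(subset=["person_id", "year_index"]).to_numpy()
    _fail(dup, df, "duplicate (person_id, year_index)")
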