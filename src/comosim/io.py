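"""Delimited-text file formats and model-parameter serialization.

Person-year cohorts round-trip through a comma-delimited table with an
explicit header (empty cells mark absent next-year covariates).  Fitted
transition-model sets serialize to a human-readable YAML document that
carries every coefficient, the QCS cut points, the categorizer bins and
the Gamma shapes, so a saved model is fully self-describing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError
from .models import (
    CciChangeParams,
    CoefTable,
    CovariateCategorizer,
    DciChangeParams,
    DeathModelParams,
    GammaSizeParams,
    TransitionModelSet,
)
from .records import COLUMNS, validate_cohort

__all__ = [
    "read_person_year_table",
    "write_person_year_table",
    "model_set_to_dict",
    "model_set_from_dict",
    "write_model_params",
    "read_model_params",
    "write_survival_curve",
    "write_life_table",
]

_INT_COLS = ("person_id", "region", "year_index", "age", "cci",
             "died", "censored")
_FLOAT_COLS = ("dci",)
_OPT_COLS = ("cci_next", "dci_next")


def _to_number(raw: pd.Series, col: str, integer: bool,
               optional: bool) -> pd.Series:
    s = raw.str.strip()
    empty = s == ""
    if empty.any() and not optional:
        line = int(raw.index[empty][0])
        raise ParseError(f"row {line}: empty cell in required column {col}")
    vals = pd.to_numeric(s.where(~empty, other=np.nan), errors="coerce")
    bad = vals.isna() & ~empty
    if bad.any():
        line = int(raw.index[bad][0])
        raise ParseError(
            f"row {line}: malformed {col} value {s[bad].iloc[0]!r}")
    if integer:
        nonint = vals.notna() & (vals % 1 != 0)
        if nonint.any():
            line = int(raw.index[nonint][0])
            raise ParseError(f"row {line}: column {col} must be integer")
    return vals


def read_person_year_table(path) -> pd.DataFrame:
    """Read and validate a long-format person-year table.

    Errors name the offending file line (the header is line 1).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != list(COLUMNS):
        raise ParseError(
            f"{path.name}: header must be exactly {','.join(COLUMNS)}")
    raw.index = raw.index + 2  # file line numbers
    df = pd.DataFrame(index=raw.index)
    for col in COLUMNS:
        integer = col in _INT_COLS
        optional = col in _OPT_COLS
        df[col] = _to_number(raw[col], col, integer and col != "cci_next",
                             optional)
    for col in _INT_COLS:
        df[col] = df[col].astype(np.int64)
    try:
        validate_cohort(df)
    except ValidationError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    return df.reset_index(drop=True)


def write_person_year_table(df: pd.DataFrame, path) -> None:
    """Write a cohort in the canonical person-year schema."""
    validate_cohort(df)
    out = df[list(COLUMNS)].copy()
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model-parameter documents
# ---------------------------------------------------------------------------

def _coef_to_dict(ct: Optional[CoefTable]) -> Optional[dict]:
    if ct is None:
        return None
    d = {"coefficients": {n: float(v) for n, v in zip(ct.names, ct.values)}}
    if ct.bse is not None:
        d["bse"] = {n: float(v) for n, v in zip(ct.names, ct.bse)}
    return d


def _coef_from_dict(d: Optional[dict]) -> Optional[CoefTable]:
    if d is None:
        return None
    return CoefTable.from_dict(d["coefficients"], d.get("bse"))


def _gamma_to_dict(gp: Optional[GammaSizeParams]) -> Optional[dict]:
    if gp is None:
        return None
    return {"shape": float(gp.shape),
            "log_shape_bse": None if gp.log_shape_bse is None
            else float(gp.log_shape_bse),
            "mean": _coef_to_dict(gp.mean)}


def _gamma_from_dict(d: Optional[dict]) -> Optional[GammaSizeParams]:
    if d is None:
        return None
    return GammaSizeParams(shape=float(d["shape"]),
                           mean=_coef_from_dict(d["mean"]),
                           log_shape_bse=d.get("log_shape_bse"))


def model_set_to_dict(models: TransitionModelSet) -> dict:
    dm = models.death
    return {
        "death": {
            "coefficients": {t: float(getattr(dm, t)) for t in dm.TERMS},
            "cut_points": {"cci": float(dm.cut_cci),
                           "dci": float(dm.cut_dci),
                           "age": float(dm.cut_age)},
            "bse": None if dm.bse is None else
                   {k: float(v) for k, v in dm.bse.items()},
        },
        "cci_change": {
            "occurrence": _coef_to_dict(models.cci.occurrence),
            "size_stratum0": _coef_to_dict(models.cci.size_stratum0),
            "size_stratum1": _coef_to_dict(models.cci.size_stratum1),
            "size_mode": models.cci.size_mode,
        },
        "dci_change": {
            "occurrence": _coef_to_dict(models.dci.occurrence),
            "direction": _coef_to_dict(models.dci.direction),
            "increase_size": _gamma_to_dict(models.dci.increase),
            "decrease_size": _gamma_to_dict(models.dci.decrease),
            "size_mode": models.dci.size_mode,
        },
        "categorizer": {
            "cci_edges": list(models.categorizer.cci_edges),
            "dci_edges": list(models.categorizer.dci_edges),
            "age_edges": list(models.categorizer.age_edges),
        },
    }


def model_set_from_dict(doc: dict) -> TransitionModelSet:
    try:
        dd = doc["death"]
        death = DeathModelParams(
            **{t: float(dd["coefficients"][t]) for t in
               DeathModelParams.TERMS},
            cut_cci=float(dd["cut_points"]["cci"]),
            cut_dci=float(dd["cut_points"]["dci"]),
            cut_age=float(dd["cut_points"]["age"]),
            bse=dd.get("bse"))
        cc = doc["cci_change"]
        cci = CciChangeParams(
            occurrence=_coef_from_dict(cc["occurrence"]),
            size_stratum0=_coef_from_dict(cc.get("size_stratum0")),
            size_stratum1=_coef_from_dict(cc.get("size_stratum1")),
            size_mode=cc.get("size_mode", "poisson"))
        dc = doc["dci_change"]
        dci = DciChangeParams(
            occurrence=_coef_from_dict(dc["occurrence"]),
            direction=_coef_from_dict(dc["direction"]),
            increase=_gamma_from_dict(dc.get("increase_size")),
            decrease=_gamma_from_dict(dc.get("decrease_size")),
            size_mode=dc.get("size_mode", "gamma"))
        cat = CovariateCategorizer(
            cci_edges=tuple(doc["categorizer"]["cci_edges"]),
            dci_edges=tuple(doc["categorizer"]["dci_edges"]),
            age_edges=tuple(doc["categorizer"]["age_edges"]))
    except KeyError as exc:
        raise ParseError(f"model document missing section/field {exc}")
    return TransitionModelSet(death, cci, dci, cat)


def write_model_params(models: TransitionModelSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_set_to_dict(models), fh, sort_keys=False)


def read_model_params(path) -> TransitionModelSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: not a model parameter document")
    return model_set_from_dict(doc)


def write_survival_curve(curve, path, start=None) -> None:
    """Long-format curve export: age, cci, dci, t, survival."""
    start = start or curve.start or (np.nan, np.nan, np.nan)
    pd.DataFrame({
        "age": start[0], "cci": start[1], "dci": start[2],
        "t": curve.times, "survival": curve.survival,
    }).to_csv(path, index=False)


def write_life_table(table, path) -> None:
    table.frame.to_csv(path, index=False)
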