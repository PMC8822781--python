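"""Validation battery: observed vs simulated survival, comorbidity
trajectories, calibration, and leave-one-region-out cross-validation.

Observed survival uses the product-limit (Kaplan-Meier) estimator on the
annual person-year follow-up, with censored rows contributing risk time
up to censoring; pointwise uncertainty is the Greenwood standard error.
Comparisons against simulated curves report pointwise differences, the
maximum absolute difference, and restricted "years lost" (the area above
the survival curve) over a 10-year horizon.

Calibration tables bin predicted probabilities into equal-frequency bins
and compare the per-bin mean prediction with the observed event fraction.
Note that DCI occurrence/direction calibration, like the corresponding
fits, excludes person-years with DCI at the -0.75 floor, where a
truncated decrease is indistinguishable from no change.

Cross-validation refits the full transition-model set on all but one
health-care region, simulates from the held-out region's observed entry
states, and compares with the held-out region's Kaplan-Meier curve.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import ValidationError
from .microsim import CohortPanel, SurvivalCurve
from .models import (
    TransitionModelSet,
    death_probability,
    dci_transition_probabilities,
    fit_transition_models,
)
from .records import DCI_FLOOR
from .synthetic import simulate_entry_states

__all__ = [
    "ComparisonReport",
    "CalibrationTable",
    "RegionCrossValidation",
    "observed_survival",
    "years_lost",
    "compare_survival",
    "observed_trajectories",
    "mean_trajectories",
    "calibration",
    "death_model_calibration",
    "dci_occurrence_calibration",
    "region_cross_validation",
]


@dataclass
class ComparisonReport:
    """Pointwise observed-vs-simulated survival comparison."""

    times: np.ndarray
    observed: np.ndarray
    simulated: np.ndarray
    se_combined: np.ndarray
    years_lost_observed: float
    years_lost_simulated: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.years_lost_observed < -1e-9 or \
                self.years_lost_simulated < -1e-9:
            raise ValidationError("years lost must be non-negative")
        if np.any(np.abs(self.diff) > 1 + 1e-9):
            raise ValidationError("survival differences must lie in [-1, 1]")

    @property
    def diff(self) -> np.ndarray:
        return self.observed - self.simulated

    @property
    def max_abs_diff(self) -> float:
        return float(np.max(np.abs(self.diff)))

    @property
    def years_lost_difference(self) -> float:
        return self.years_lost_observed - self.years_lost_simulated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times, "observed": self.observed,
            "simulated": self.simulated, "difference": self.diff,
            "se_combined": self.se_combined,
        })


@dataclass
class CalibrationTable:
    """Equal-frequency calibration bins for a binary-outcome model."""

    frame: pd.DataFrame  # bin, p_low, p_high, mean_predicted, frac_observed, n
    n_bins_requested: int

    def __post_init__(self) -> None:
        f = self.frame
        bad = (f["frac_observed"] < 0) | (f["frac_observed"] > 1)
        if bad.any():
            raise ValidationError("observed fractions must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return int(self.frame["n"].sum())


def _entry_mask(cohort: pd.DataFrame, entry_filter: Optional[dict]
                ) -> pd.Series:
    entry = cohort[cohort["year_index"] == 0]
    mask = pd.Series(True, index=entry.index)
    for key, val in (entry_filter or {}).items():
        if key not in ("age", "cci", "dci", "region"):
            raise ValidationError(f"unknown entry filter key {key!r}")
        vals = np.atleast_1d(val)
        if key == "dci":
            mask &= entry[key].apply(
                lambda x: bool(np.any(np.isclose(x, vals))))
        else:
            mask &= entry[key].isin(vals)
    return entry.loc[mask, "person_id"]


def observed_survival(cohort: pd.DataFrame,
                      entry_filter: Optional[dict] = None) -> SurvivalCurve:
    """Kaplan-Meier survival of a cohort subgroup on annual follow-up.

    ``entry_filter`` selects individuals by their entry-year state, e.g.
    ``{"age": [65, 66], "cci": 0}``; None keeps everyone.
    """
    persons = _entry_mask(cohort, entry_filter)
    sub = cohort[cohort["person_id"].isin(persons)]
    if len(sub) == 0:
        raise ValidationError("empty stratum: no individuals match filter")
    g = sub.groupby("person_id")
    durations = (g["year_index"].max() + 1).to_numpy()
    events = g["died"].max().to_numpy()
    T = int(durations.max())
    timeline = np.arange(T + 1)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events, timeline=timeline)
    s = kmf.survival_function_.iloc[:, 0].to_numpy()
    # Greenwood pointwise variance from the event table.
    tab = kmf.event_table
    d = tab["observed"].to_numpy(dtype=float)
    n_risk = tab["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_risk > d, d / (n_risk * (n_risk - d)), 0.0)
    cum = np.cumsum(inc)
    cum_on_timeline = np.interp(timeline, tab.index.to_numpy(dtype=float),
                                cum)
    se = s * np.sqrt(cum_on_timeline)
    return SurvivalCurve(timeline, s, n=len(durations), se=se)


def _curve_values(curve: SurvivalCurve, horizon: int) -> np.ndarray:
    s = curve.survival
    if len(s) >= horizon + 1:
        return s[:horizon + 1]
    if np.isclose(s[-1], 0.0):
        return np.concatenate([s, np.zeros(horizon + 1 - len(s))])
    raise ValidationError(
        f"curve ends at t={len(s) - 1} before horizon {horizon}")


def years_lost(curve: SurvivalCurve, horizon: int = 10) -> float:
    """Area above the survival curve during the first ``horizon`` years."""
    s = _curve_values(curve, horizon)
    return float(horizon - np.trapezoid(s, np.arange(horizon + 1)))


def _curve_se(curve: SurvivalCurve, horizon: int) -> np.ndarray:
    if curve.se is None:
        return np.zeros(horizon + 1)
    se = curve.se
    if len(se) >= horizon + 1:
        return se[:horizon + 1]
    return np.concatenate([se, np.zeros(horizon + 1 - len(se))])


def compare_survival(observed: SurvivalCurve, simulated: SurvivalCurve,
                     horizon: int = 10, note: str = "") -> ComparisonReport:
    """Pointwise comparison of two survival curves over a common horizon.

    Swapping the two curves negates every pointwise difference (the
    machinery is symmetric); ``se_combined`` is the root sum of squares of
    the curves' pointwise standard errors.
    """
    obs = _curve_values(observed, horizon)
    sim = _curve_values(simulated, horizon)
    se = np.sqrt(_curve_se(observed, horizon) ** 2
                 + _curve_se(simulated, horizon) ** 2)
    return ComparisonReport(
        times=np.arange(horizon + 1), observed=obs, simulated=sim,
        se_combined=se,
        years_lost_observed=years_lost(observed, horizon),
        years_lost_simulated=years_lost(simulated, horizon),
        note=note)


def observed_trajectories(cohort: pd.DataFrame,
                          entry_filter: Optional[dict] = None
                          ) -> pd.DataFrame:
    """Per-year mean CCI and DCI among individuals still under follow-up."""
    persons = _entry_mask(cohort, entry_filter)
    sub = cohort[cohort["person_id"].isin(persons)]
    if len(sub) == 0:
        raise ValidationError("empty stratum: no individuals match filter")
    g = sub.groupby("year_index")
    out = pd.DataFrame({
        "t": g.size().index,
        "n": g.size().to_numpy(),
        "mean_cci": g["cci"].mean().to_numpy(),
        "sd_cci": g["cci"].std(ddof=0).to_numpy(),
        "mean_dci": g["dci"].mean().to_numpy(),
        "sd_dci": g["dci"].std(ddof=0).to_numpy(),
    }).reset_index(drop=True)
    return out


def mean_trajectories(cohort: pd.DataFrame,
                      panels: Dict[object, CohortPanel],
                      filters: Dict[object, Optional[dict]]) -> pd.DataFrame:
    """Observed vs simulated mean CCI/DCI per year, by entry stratum.

    ``panels`` maps a stratum key to the simulated :class:`CohortPanel`;
    ``filters`` maps the same keys to entry-state filters selecting the
    observed stratum.  Year/stratum cells with no observed survivors are
    simply absent from the output.
    """
    if set(panels) != set(filters):
        raise ValidationError("panels and filters must share strata keys")
    frames = []
    for key, panel in panels.items():
        obs = observed_trajectories(cohort, filters[key])
        t_max = min(int(obs["t"].max()), len(panel.times) - 1)
        obs = obs[obs["t"] <= t_max].copy()
        t = obs["t"].to_numpy()
        n_sim = np.maximum(panel.n_alive[t], 1)
        obs["sim_mean_cci"] = panel.mean_cci[t]
        obs["sim_mean_dci"] = panel.mean_dci[t]
        obs["diff_cci"] = obs["mean_cci"] - obs["sim_mean_cci"]
        obs["diff_dci"] = obs["mean_dci"] - obs["sim_mean_dci"]
        obs["se_combined_cci"] = np.sqrt(
            obs["sd_cci"] ** 2 / obs["n"] + panel.sd_cci[t] ** 2 / n_sim)
        obs["se_combined_dci"] = np.sqrt(
            obs["sd_dci"] ** 2 / obs["n"] + panel.sd_dci[t] ** 2 / n_sim)
        obs.insert(0, "stratum", key)
        frames.append(obs)
    return pd.concat(frames, ignore_index=True)


def calibration(predicted: Sequence[float], outcomes: Sequence[int],
                n_bins: int = 10) -> CalibrationTable:
    """Equal-frequency calibration table for predicted probabilities."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) == 0:
        raise ValidationError("calibration requires non-empty input")
    if len(p) != len(y):
        raise ValidationError("predicted/outcomes length mismatch")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if np.any((p < 0) | (p > 1)) or not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("need probabilities in [0,1], binary outcomes")
    try:
        bins = pd.qcut(p, q=n_bins, duplicates="drop")
    except ValueError:
        bins = pd.Series(pd.Categorical(np.zeros(len(p), dtype=int)))
    codes = pd.Categorical(bins).codes.astype(int)
    codes = np.where(codes < 0, 0, codes)
    n_eff = int(codes.max()) + 1
    if n_eff < n_bins:
        warnings.warn(
            f"calibration: only {n_eff} distinct bins for {n_bins} "
            "requested (ties in predictions)", RuntimeWarning)
    rows = []
    for b in range(n_eff):
        m = codes == b
        rows.append({
            "bin": b,
            "p_low": float(p[m].min()),
            "p_high": float(p[m].max()),
            "mean_predicted": float(p[m].mean()),
            "frac_observed": float(y[m].mean()),
            "n": int(m.sum()),
        })
    return CalibrationTable(pd.DataFrame(rows), n_bins)


def death_model_calibration(cohort: pd.DataFrame,
                            models: TransitionModelSet,
                            n_bins: int = 10) -> CalibrationTable:
    """Calibration of the annual death model on every person-year."""
    p = death_probability(cohort["age"].to_numpy(float),
                          cohort["cci"].to_numpy(float),
                          cohort["dci"].to_numpy(float), models.death)
    return calibration(p, cohort["died"].to_numpy(float), n_bins)


def dci_occurrence_calibration(cohort: pd.DataFrame,
                               models: TransitionModelSet,
                               n_bins: int = 10) -> CalibrationTable:
    """Calibration of the DCI any-change model on completed person-years.

    Rows with DCI at the floor are excluded, mirroring the fit.
    """
    rows = cohort[cohort["dci_next"].notna()
                  & ~np.isclose(cohort["dci"], DCI_FLOOR)]
    if len(rows) == 0:
        raise ValidationError("no usable rows for DCI calibration")
    p, _ = dci_transition_probabilities(
        rows["age"].to_numpy(float), rows["cci"].to_numpy(float),
        rows["dci"].to_numpy(float), models.dci, models.categorizer)
    y = (~np.isclose(rows["dci_next"].to_numpy(float),
                     rows["dci"].to_numpy(float))).astype(float)
    return calibration(p, y, n_bins)


@dataclass
class RegionCrossValidation:
    """Per-region leave-one-out comparison reports."""

    reports: Dict[int, ComparisonReport]
    skipped: List[int] = field(default_factory=list)


def region_cross_validation(cohort: pd.DataFrame, seed: int,
                            horizon: int = 10,
                            n_years: Optional[int] = None,
                            replicates: int = 5,
                            fit_procedure: Callable[
                                [pd.DataFrame], TransitionModelSet
                            ] = fit_transition_models,
                            regions: Optional[Sequence[int]] = None
                            ) -> RegionCrossValidation:
    """Leave-one-region-out cross-validation of the whole pipeline.

    For each region, transition models are fitted on the other regions'
    person-years, survival is simulated from the held-out region's entry
    states (each replicated ``replicates`` times), and compared with the
    held-out region's Kaplan-Meier curve over ``horizon`` years.
    """
    present = sorted(int(r) for r in cohort["region"].unique())
    if len(present) < 2:
        raise ValidationError(
            "cross-validation requires at least 2 regions")
    wanted = present if regions is None else [int(r) for r in regions]
    n_years = n_years or (horizon + 1)
    reports: Dict[int, ComparisonReport] = {}
    skipped: List[int] = []
    for r in wanted:
        held = cohort[cohort["region"] == r]
        if len(held) == 0:
            skipped.append(r)
            continue
        train = cohort[cohort["region"] != r]
        models = fit_procedure(train)
        entry = held[held["year_index"] == 0]
        ages = entry["age"].to_numpy()
        ccis = entry["cci"].to_numpy()
        dcis = entry["dci"].to_numpy()
        # Seed the held-out simulation by the content of the held-out
        # entry states, not the region label, so permuting region labels
        # permutes the reports without changing them.
        key = zlib.crc32(np.ascontiguousarray(
            np.column_stack([ages, ccis, dcis]).astype(float)).tobytes())
        sim = simulate_entry_states(
            ages, ccis, dcis, models, n_years,
            seed=(int(seed) + key) % (2 ** 31), replicates=replicates)
        obs = observed_survival(held)
        reports[r] = compare_survival(obs, sim, horizon=horizon,
                                      note=f"held-out region {r}")
    return RegionCrossValidation(reports, skipped)
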