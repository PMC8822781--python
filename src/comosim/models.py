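"""Annual transition models: death, CCI change, and DCI change.

Three generalised linear models drive the yearly state updates of the
microsimulation:

* **Death** — a person-year life-table logistic model.  The linear
  predictor combines a linear age term with quadratic-constant spline
  (QCS) transforms of CCI (cut point 7) and DCI (cut point 14), plus
  interactions of each comorbidity spline with a QCS in age (cut point
  100) that lets the comorbidity effect attenuate at high ages and vanish
  from age 100 onward.

* **CCI change** — a two-step procedure on categorised covariates:
  (1) logistic occurrence of any CCI increase during the year;
  (2) size of the increase, modelled as 1 + Poisson with log link, with
  two separate Poisson models for current CCI = 0 and CCI > 0.

* **DCI change** — a four-step procedure: (1) logistic occurrence of any
  change; (2) logistic direction (increase vs decrease) given a change;
  (3, 4) size of the change per direction from a Gamma model with log
  link.  Raw Gamma sizes are rounded to the 0.25 DCI grid (minimum step
  0.25) and decreases are truncated so DCI never falls below -0.75.

Because recorded DCI steps live on the 0.25 grid and decreases can hit
the -0.75 floor, the Gamma size models are estimated by interval-censored
maximum likelihood: a recorded step of v contributes the probability mass
of the rounding interval around v, and a floor-hit contributes the upper
tail.  Rows with current DCI exactly at the floor are excluded from the
occurrence and direction fits, since a drawn decrease there is truncated
to no change and the indicators are therefore not cleanly observable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    DegenerateFitError,
    EstimationError,
    StratumError,
    ValidationError,
)
from .qcs import qcs_value
from .records import AGE_MAX, AGE_MIN, DCI_FLOOR, DCI_STEP

__all__ = [
    "CUT_CCI",
    "CUT_DCI",
    "CUT_AGE",
    "CoefTable",
    "CovariateCategorizer",
    "DeathModelParams",
    "CciChangeParams",
    "GammaSizeParams",
    "DciChangeParams",
    "TransitionModelSet",
    "death_probability",
    "death_linear_predictor",
    "fit_death_model",
    "cci_change_probability",
    "sample_cci_increment",
    "fit_cci_models",
    "dci_transition_probabilities",
    "sample_dci_step",
    "fit_dci_models",
    "fit_transition_models",
    "constant_models",
]

CUT_CCI = 7.0
CUT_DCI = 14.0
CUT_AGE = 100.0

# Recorded DCI steps are grid values; half-width of the rounding interval.
_HALF_GRID = DCI_STEP / 2.0


def _check_covariates(age, cci, dci) -> None:
    age = np.asarray(age, dtype=float)
    cci = np.asarray(cci, dtype=float)
    dci = np.asarray(dci, dtype=float)
    if not (np.all(np.isfinite(age)) and np.all(np.isfinite(cci))
            and np.all(np.isfinite(dci))):
        raise ValidationError("covariates must be finite")
    if np.any(age < AGE_MIN) or np.any(age > AGE_MAX):
        raise ValidationError(f"age outside [{AGE_MIN}, {AGE_MAX}]")
    if np.any(cci < 0):
        raise ValidationError("cci must be >= 0")
    if np.any(dci < DCI_FLOOR - 1e-9):
        raise ValidationError(f"dci below floor {DCI_FLOOR}")


# ---------------------------------------------------------------------------
# Coefficient tables and covariate categorisation
# ---------------------------------------------------------------------------

@dataclass
class CoefTable:
    """Named coefficient vector with optional estimated standard errors."""

    names: Tuple[str, ...]
    values: np.ndarray
    bse: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bse is not None:
            self.bse = np.asarray(self.bse, dtype=float)
        if len(self.names) != len(self.values):
            raise ValidationError("coefficient names/values length mismatch")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    @classmethod
    def from_dict(cls, d: Dict[str, float],
                  bse: Optional[Dict[str, float]] = None) -> "CoefTable":
        names = tuple(d.keys())
        values = np.array([d[n] for n in names], dtype=float)
        b = None if bse is None else np.array([bse[n] for n in names])
        return cls(names, values, b)


@dataclass(frozen=True)
class CovariateCategorizer:
    """Bins age, CCI and DCI into ordered categories for the change models.

    ``cci_edges`` and ``age_edges`` define left-closed bins (a value equal
    to an edge starts a new category); ``dci_edges`` define right-closed
    bins, so the default ``(0.0, 1.0, 3.0)`` yields
    {<=0, (0,1], (1,3], >3}.  Defaults: CCI {0, 1, 2, >=3},
    age {65-74, 75-84, >=85}.
    """

    cci_edges: Tuple[float, ...] = (1.0, 2.0, 3.0)
    dci_edges: Tuple[float, ...] = (0.0, 1.0, 3.0)
    age_edges: Tuple[float, ...] = (75.0, 85.0)

    def __post_init__(self) -> None:
        for name in ("cci_edges", "dci_edges", "age_edges"):
            edges = np.asarray(getattr(self, name), dtype=float)
            if len(edges) == 0 or np.any(np.diff(edges) <= 0):
                raise ValidationError(f"{name} must be strictly increasing")

    def age_code(self, age) -> np.ndarray:
        return np.searchsorted(self.age_edges, np.asarray(age, float),
                               side="right")

    def cci_code(self, cci) -> np.ndarray:
        return np.searchsorted(self.cci_edges, np.asarray(cci, float),
                               side="right")

    def dci_code(self, dci) -> np.ndarray:
        return np.searchsorted(self.dci_edges, np.asarray(dci, float),
                               side="left")

    def design_names(self) -> Tuple[str, ...]:
        names = ["intercept"]
        names += [f"age_{k}" for k in range(1, len(self.age_edges) + 1)]
        names += [f"cci_{k}" for k in range(1, len(self.cci_edges) + 1)]
        names += [f"dci_{k}" for k in range(1, len(self.dci_edges) + 1)]
        return tuple(names)

    def column(self, name: str, age, cci, dci) -> np.ndarray:
        """Design column by name: intercept or a category indicator."""
        age, cci, dci = np.broadcast_arrays(
            np.atleast_1d(np.asarray(age, float)),
            np.atleast_1d(np.asarray(cci, float)),
            np.atleast_1d(np.asarray(dci, float)))
        if name == "intercept":
            return np.ones(age.shape)
        factor, code = name.rsplit("_", 1)
        k = int(code)
        if factor == "age":
            return (self.age_code(age) == k).astype(float)
        if factor == "cci":
            return (self.cci_code(cci) == k).astype(float)
        if factor == "dci":
            return (self.dci_code(dci) == k).astype(float)
        raise ValidationError(f"unknown design column {name!r}")

    def design(self, age, cci, dci) -> pd.DataFrame:
        _check_covariates(age, cci, dci)
        return pd.DataFrame(
            {n: self.column(n, age, cci, dci) for n in self.design_names()}
        )


def _categorized_lp(age, cci, dci, coefs: CoefTable,
                    cat: CovariateCategorizer) -> np.ndarray:
    _check_covariates(age, cci, dci)
    lp = 0.0
    for name, value in zip(coefs.names, coefs.values):
        lp = lp + value * cat.column(name, age, cci, dci)
    return np.asarray(lp, dtype=float)


# ---------------------------------------------------------------------------
# Death model
# ---------------------------------------------------------------------------

@dataclass
class DeathModelParams:
    """Life-table logistic mortality model on the QCS design.

    The linear predictor is::

        eta = intercept + beta_age * age
            + beta_cci * g(cci; 7) + beta_dci * g(dci; 14)
            + gamma_cci * g(age; 100) * g(cci; 7)
            + gamma_dci * g(age; 100) * g(dci; 14)

    where g is the decreasing QCS basis, so coefficients on g are
    negative when higher comorbidity raises mortality.  ``intercept`` may
    be +/-inf only for the forced constant models used in oracle tests.
    """

    intercept: float
    beta_age: float
    beta_cci: float
    beta_dci: float
    gamma_cci: float
    gamma_dci: float
    cut_cci: float = CUT_CCI
    cut_dci: float = CUT_DCI
    cut_age: float = CUT_AGE
    bse: Optional[Dict[str, float]] = None

    TERMS = ("intercept", "beta_age", "beta_cci", "beta_dci",
             "gamma_cci", "gamma_dci")

    def coef_vector(self) -> np.ndarray:
        return np.array([getattr(self, t) for t in self.TERMS], dtype=float)


def _death_design(age, cci, dci, params: DeathModelParams) -> np.ndarray:
    g_cci = qcs_value(cci, params.cut_cci)
    g_dci = qcs_value(dci, params.cut_dci)
    g_age = qcs_value(age, params.cut_age)
    age = np.asarray(age, dtype=float)
    cols = np.broadcast_arrays(
        np.ones_like(age, dtype=float), age, g_cci, g_dci,
        g_age * g_cci, g_age * g_dci,
    )
    return np.column_stack([np.ravel(c) for c in cols])


def death_linear_predictor(age, cci, dci, params: DeathModelParams):
    _check_covariates(age, cci, dci)
    X = _death_design(age, cci, dci, params)
    eta = X @ params.coef_vector()
    if np.isscalar(age) and np.isscalar(cci) and np.isscalar(dci):
        return float(eta[0])
    shape = np.broadcast(np.asarray(age), np.asarray(cci),
                         np.asarray(dci)).shape
    return eta.reshape(shape)


def death_probability(age, cci, dci, params: DeathModelParams):
    """Annual probability of death from the QCS logistic model."""
    return expit(death_linear_predictor(age, cci, dci, params))


def _check_binary_outcome(y: np.ndarray, label: str) -> None:
    if len(y) == 0:
        raise DegenerateFitError(f"{label}: no observations")
    if len(np.unique(y)) < 2:
        raise DegenerateFitError(
            f"{label}: outcome has a single level ({y[0]:g}); "
            "cannot fit a logistic model"
        )


def _fit_glm(y, X: pd.DataFrame, family, label: str):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(np.asarray(y, float), X, family=family).fit()
    except PerfectSeparationError as exc:  # pragma: no cover - data dependent
        raise EstimationError(f"{label}: perfect separation ({exc})")
    if not getattr(res, "converged", True) or not np.all(
            np.isfinite(res.params)):
        raise EstimationError(
            f"{label}: IRLS failed to converge; "
            f"offending terms {list(X.columns)}"
        )
    return res


def fit_death_model(table: pd.DataFrame,
                    cut_cci: float = CUT_CCI,
                    cut_dci: float = CUT_DCI,
                    cut_age: float = CUT_AGE) -> DeathModelParams:
    """Maximum-likelihood logistic fit of ``died`` on the QCS design."""
    if len(table) == 0:
        raise DegenerateFitError("death model: empty table")
    y = table["died"].to_numpy(dtype=float)
    _check_binary_outcome(y, "death model")
    params0 = DeathModelParams(0, 0, 0, 0, 0, 0, cut_cci, cut_dci, cut_age)
    X = pd.DataFrame(
        _death_design(table["age"].to_numpy(float),
                      table["cci"].to_numpy(float),
                      table["dci"].to_numpy(float), params0),
        columns=DeathModelParams.TERMS,
    )
    res = _fit_glm(y, X, sm.families.Binomial(), "death model")
    coefs = dict(zip(DeathModelParams.TERMS, np.asarray(res.params)))
    bse = dict(zip(DeathModelParams.TERMS, np.asarray(res.bse)))
    return DeathModelParams(cut_cci=cut_cci, cut_dci=cut_dci,
                            cut_age=cut_age, bse=bse, **coefs)


# ---------------------------------------------------------------------------
# CCI change models
# ---------------------------------------------------------------------------

@dataclass
class CciChangeParams:
    """Two-step CCI change model on categorised covariates.

    ``size_mode`` is ``"poisson"`` (size = 1 + Poisson(exp(lp)), with
    separate coefficient tables for current CCI = 0 and CCI > 0) or
    ``"fixed_one"`` (degenerate increment of exactly 1, used by the exact
    finite-chain oracle).
    """

    occurrence: CoefTable
    size_stratum0: Optional[CoefTable] = None
    size_stratum1: Optional[CoefTable] = None
    size_mode: str = "poisson"

    def __post_init__(self) -> None:
        if self.size_mode not in ("poisson", "fixed_one"):
            raise ValidationError(f"bad CCI size_mode {self.size_mode!r}")
        if self.size_mode == "poisson" and (
                self.size_stratum0 is None or self.size_stratum1 is None):
            raise ValidationError("poisson size mode needs both strata")


def cci_change_probability(age, cci, dci, params: CciChangeParams,
                           categorizer: CovariateCategorizer):
    lp = _categorized_lp(age, cci, dci, params.occurrence, categorizer)
    p = expit(lp)
    if np.isscalar(age) and np.isscalar(cci) and np.isscalar(dci):
        return float(p[0])
    return p


def sample_cci_increment(age, cci, dci, params: CciChangeParams,
                         categorizer: CovariateCategorizer,
                         rng: np.random.Generator):
    """Draw the size of a CCI increase (>= 1); call only when a change occurs."""
    scalar = np.isscalar(cci)
    age = np.atleast_1d(np.asarray(age, float))
    cci = np.atleast_1d(np.asarray(cci, float))
    dci = np.atleast_1d(np.asarray(dci, float))
    age, cci, dci = np.broadcast_arrays(age, cci, dci)
    if params.size_mode == "fixed_one":
        out = np.ones(cci.shape, dtype=np.int64)
    else:
        mean = np.empty(cci.shape, dtype=float)
        m0 = cci == 0
        if m0.any():
            mean[m0] = np.exp(_categorized_lp(
                age[m0], cci[m0], dci[m0], params.size_stratum0, categorizer))
        if (~m0).any():
            mean[~m0] = np.exp(_categorized_lp(
                age[~m0], cci[~m0], dci[~m0], params.size_stratum1,
                categorizer))
        out = 1 + rng.poisson(mean)
    return int(out[0]) if scalar else out


def _prune_rank_deficient(X: pd.DataFrame) -> pd.DataFrame:
    """Greedily keep columns that increase matrix rank (in given order)."""
    kept: list[str] = []
    arr = X.to_numpy(dtype=float)
    rank = 0
    for j, name in enumerate(X.columns):
        trial = arr[:, [X.columns.get_loc(k) for k in kept] + [j]]
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept.append(name)
            rank = r
    return X[kept]


def _fit_poisson_size(sizes: np.ndarray, X: pd.DataFrame,
                      label: str) -> CoefTable:
    if len(sizes) == 0:
        raise StratumError(f"{label}: no changed rows in stratum")
    X = _prune_rank_deficient(X)
    if sizes.sum() == 0:
        # Every change had size exactly 1: the Poisson mean is on the
        # boundary (log-mean -> -inf).  Flag with a large negative
        # intercept; the fitted mean is numerically zero.
        values = np.zeros(X.shape[1])
        values[list(X.columns).index("intercept")] = -30.0
        warnings.warn(
            f"{label}: all change sizes are 1; Poisson log-mean is on the "
            "-inf boundary, returning intercept -30", RuntimeWarning)
        return CoefTable(tuple(X.columns), values, None)
    res = _fit_glm(sizes, X, sm.families.Poisson(), label)
    return CoefTable(tuple(X.columns), np.asarray(res.params),
                     np.asarray(res.bse))


def fit_cci_models(table: pd.DataFrame,
                   categorizer: Optional[CovariateCategorizer] = None
                   ) -> CciChangeParams:
    """Fit the CCI occurrence and size models from completed person-years."""
    cat = categorizer or CovariateCategorizer()
    rows = table[table["cci_next"].notna()]
    if len(rows) == 0:
        raise DegenerateFitError("CCI models: no completed person-years")
    age = rows["age"].to_numpy(float)
    cci = rows["cci"].to_numpy(float)
    dci = rows["dci"].to_numpy(float)
    changed = rows["cci_next"].to_numpy(float) > cci

    _check_binary_outcome(changed.astype(float), "CCI occurrence")
    X = _prune_rank_deficient(cat.design(age, cci, dci))
    res = _fit_glm(changed.astype(float), X, sm.families.Binomial(),
                   "CCI occurrence")
    occurrence = CoefTable(tuple(X.columns), np.asarray(res.params),
                           np.asarray(res.bse))

    sizes = (rows["cci_next"].to_numpy(float) - cci - 1.0)[changed]
    age_c, cci_c, dci_c = age[changed], cci[changed], dci[changed]
    tables = []
    for stratum, mask in (("CCI size (CCI=0)", cci_c == 0),
                          ("CCI size (CCI>0)", cci_c > 0)):
        Xs = cat.design(age_c[mask], cci_c[mask], dci_c[mask])
        tables.append(_fit_poisson_size(sizes[mask], Xs, stratum))
    return CciChangeParams(occurrence, tables[0], tables[1], "poisson")


# ---------------------------------------------------------------------------
# DCI change models
# ---------------------------------------------------------------------------

@dataclass
class GammaSizeParams:
    """Gamma size sub-model: shape and log-link mean coefficients."""

    shape: float
    mean: CoefTable
    log_shape_bse: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValidationError("Gamma shape must be strictly positive")


@dataclass
class DciChangeParams:
    """Four-step DCI change model.

    ``size_mode`` is ``"gamma"`` (rounded, floor-truncated Gamma steps) or
    ``"fixed_grid"`` (degenerate step of one 0.25 grid unit).
    """

    occurrence: CoefTable
    direction: CoefTable
    increase: Optional[GammaSizeParams] = None
    decrease: Optional[GammaSizeParams] = None
    size_mode: str = "gamma"

    def __post_init__(self) -> None:
        if self.size_mode not in ("gamma", "fixed_grid"):
            raise ValidationError(f"bad DCI size_mode {self.size_mode!r}")
        if self.size_mode == "gamma" and (
                self.increase is None or self.decrease is None):
            raise ValidationError("gamma size mode needs both directions")


def dci_transition_probabilities(age, cci, dci, params: DciChangeParams,
                                 categorizer: CovariateCategorizer):
    """(P(change), P(increase | change)) at the given state."""
    p_change = expit(_categorized_lp(age, cci, dci, params.occurrence,
                                     categorizer))
    p_inc = expit(_categorized_lp(age, cci, dci, params.direction,
                                  categorizer))
    if np.isscalar(age) and np.isscalar(cci) and np.isscalar(dci):
        return float(p_change[0]), float(p_inc[0])
    return p_change, p_inc


def sample_dci_step(age, cci, dci, direction: str, params: DciChangeParams,
                    categorizer: CovariateCategorizer,
                    rng: np.random.Generator):
    """Draw a DCI step magnitude on the 0.25 grid for the given direction.

    The raw Gamma draw is rounded to the nearest 0.25 with minimum 0.25;
    a decrease is truncated so the resulting DCI never falls below -0.75
    (at the floor itself the step truncates to 0).
    """
    if direction not in ("increase", "decrease"):
        raise ValidationError(f"unknown direction {direction!r}")
    scalar = np.isscalar(dci)
    age = np.atleast_1d(np.asarray(age, float))
    cci = np.atleast_1d(np.asarray(cci, float))
    dci = np.atleast_1d(np.asarray(dci, float))
    age, cci, dci = np.broadcast_arrays(age, cci, dci)
    if params.size_mode == "fixed_grid":
        step = np.full(dci.shape, DCI_STEP)
    else:
        gp = params.increase if direction == "increase" else params.decrease
        mu = np.exp(_categorized_lp(age, cci, dci, gp.mean, categorizer))
        if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
            raise ValidationError("predicted Gamma mean must be positive")
        raw = rng.gamma(shape=gp.shape, scale=mu / gp.shape, size=dci.shape)
        step = np.maximum(DCI_STEP, np.round(raw / DCI_STEP) * DCI_STEP)
    if direction == "decrease":
        step = np.minimum(step, dci - DCI_FLOOR)
        step = np.round(step / DCI_STEP) * DCI_STEP
    return float(step[0]) if scalar else step


def _gamma_intervals(v: np.ndarray, censored: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Likelihood intervals for recorded grid steps.

    A recorded step v arises from raw draws rounding to v: the interval is
    (v - 0.125, v + 0.125], except v = 0.25 which also absorbs all smaller
    draws (minimum-step clamp), giving (0, 0.375].  A floor-hit (censored)
    step means the raw draw was anywhere above the lower rounding bound.
    """
    lo = np.where(v >= 2 * DCI_STEP - 1e-9, v - _HALF_GRID, 0.0)
    hi = np.where(censored, np.inf, v + _HALF_GRID)
    return lo, hi


def _gamma_interval_negll(theta: np.ndarray, X: np.ndarray,
                          lo: np.ndarray, hi: np.ndarray) -> float:
    beta, logk = theta[:-1], theta[-1]
    k = np.exp(logk)
    mu = np.exp(np.clip(X @ beta, -30, 30))
    scale = mu / k
    p_hi = np.where(np.isinf(hi), 1.0,
                    scipy.stats.gamma.cdf(hi, a=k, scale=scale))
    p_lo = scipy.stats.gamma.cdf(lo, a=k, scale=scale)
    p = np.clip(p_hi - p_lo, 1e-300, None)
    return -float(np.sum(np.log(p)))


def _fit_gamma_interval(v: np.ndarray, censored: np.ndarray,
                        X: pd.DataFrame, label: str) -> GammaSizeParams:
    if len(v) == 0:
        raise StratumError(f"{label}: no changed rows in this direction")
    X = _prune_rank_deficient(X)
    Xa = X.to_numpy(dtype=float)
    # Initialise from a plain Gamma GLM on the recorded values.
    res = _fit_glm(v, X, sm.families.Gamma(link=sm.families.links.Log()),
                   label)
    mu0 = np.exp(np.asarray(res.fittedvalues))
    r = v / np.clip(mu0, 1e-12, None)
    k0 = 1.0 / max(np.var(np.log(np.clip(r, 1e-6, None))), 1e-3)
    k0 = float(np.clip(k0, 0.1, 50.0))
    theta0 = np.concatenate([np.asarray(res.params), [np.log(k0)]])
    lo, hi = _gamma_intervals(v, censored)
    opt = scipy.optimize.minimize(
        _gamma_interval_negll, theta0, args=(Xa, lo, hi), method="L-BFGS-B")
    if not opt.success:
        raise EstimationError(f"{label}: interval ML failed ({opt.message})")
    hess = approx_hess1(opt.x, _gamma_interval_negll, args=(Xa, lo, hi))
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(len(opt.x), np.nan)
    mean = CoefTable(tuple(X.columns), opt.x[:-1], se[:-1])
    return GammaSizeParams(shape=float(np.exp(opt.x[-1])), mean=mean,
                           log_shape_bse=float(se[-1]))


def fit_dci_models(table: pd.DataFrame,
                   categorizer: Optional[CovariateCategorizer] = None
                   ) -> DciChangeParams:
    """Fit the DCI occurrence, direction and size models."""
    cat = categorizer or CovariateCategorizer()
    rows = table[table["dci_next"].notna()]
    if len(rows) == 0:
        raise DegenerateFitError("DCI models: no completed person-years")
    age = rows["age"].to_numpy(float)
    cci = rows["cci"].to_numpy(float)
    dci = rows["dci"].to_numpy(float)
    dci_next = rows["dci_next"].to_numpy(float)
    at_floor = np.isclose(dci, DCI_FLOOR)
    changed = ~np.isclose(dci_next, dci)

    # Occurrence & direction: rows at the DCI floor are excluded, since a
    # truncated decrease there is indistinguishable from no change.
    obs = ~at_floor
    _check_binary_outcome(changed[obs].astype(float), "DCI occurrence")
    Xo = _prune_rank_deficient(cat.design(age[obs], cci[obs], dci[obs]))
    res = _fit_glm(changed[obs].astype(float), Xo, sm.families.Binomial(),
                   "DCI occurrence")
    occurrence = CoefTable(tuple(Xo.columns), np.asarray(res.params),
                           np.asarray(res.bse))

    ch = obs & changed
    inc = dci_next > dci
    _check_binary_outcome(inc[ch].astype(float), "DCI direction")
    Xd = _prune_rank_deficient(cat.design(age[ch], cci[ch], dci[ch]))
    resd = _fit_glm(inc[ch].astype(float), Xd, sm.families.Binomial(),
                    "DCI direction")
    direction = CoefTable(tuple(Xd.columns), np.asarray(resd.params),
                          np.asarray(resd.bse))

    # Sizes use every changed row (increases from the floor are clean).
    inc_rows = changed & inc
    dec_rows = changed & ~inc
    if not inc_rows.any():
        raise StratumError("DCI size: no increases observed")
    if not dec_rows.any():
        raise StratumError("DCI size: no decreases observed")
    v_inc = dci_next[inc_rows] - dci[inc_rows]
    increase = _fit_gamma_interval(
        v_inc, np.zeros(v_inc.shape, dtype=bool),
        cat.design(age[inc_rows], cci[inc_rows], dci[inc_rows]),
        "DCI increase size")
    v_dec = dci[dec_rows] - dci_next[dec_rows]
    floor_hit = np.isclose(dci_next[dec_rows], DCI_FLOOR)
    decrease = _fit_gamma_interval(
        v_dec, floor_hit,
        cat.design(age[dec_rows], cci[dec_rows], dci[dec_rows]),
        "DCI decrease size")
    return DciChangeParams(occurrence, direction, increase, decrease, "gamma")


# ---------------------------------------------------------------------------
# Full model set
# ---------------------------------------------------------------------------

@dataclass
class TransitionModelSet:
    """All fitted parameters driving one year of state transitions."""

    death: DeathModelParams
    cci: CciChangeParams
    dci: DciChangeParams
    categorizer: CovariateCategorizer = field(
        default_factory=CovariateCategorizer)


def fit_transition_models(table: pd.DataFrame,
                          categorizer: Optional[CovariateCategorizer] = None
                          ) -> TransitionModelSet:
    """Fit death, CCI and DCI models from one person-year table."""
    cat = categorizer or CovariateCategorizer()
    return TransitionModelSet(
        death=fit_death_model(table),
        cci=fit_cci_models(table, cat),
        dci=fit_dci_models(table, cat),
        categorizer=cat,
    )


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def constant_models(q_death: float,
                    p_cci_change: float = 0.0,
                    p_dci_change: float = 0.0,
                    p_increase: float = 0.5,
                    cci_size_mode: str = "fixed_one",
                    dci_size_mode: str = "fixed_grid",
                    categorizer: Optional[CovariateCategorizer] = None
                    ) -> TransitionModelSet:
    """A model set with state-independent transition probabilities.

    Useful for closed-form checks: death probability is q_death at every
    state, change probabilities are constant, and change sizes are
    degenerate (CCI +1, DCI one grid unit) unless other modes are given.
    Probabilities of exactly 0 or 1 are encoded as infinite intercepts.
    """
    cat = categorizer or CovariateCategorizer()
    death = DeathModelParams(_logit(q_death), 0, 0, 0, 0, 0)
    occ_c = CoefTable(("intercept",), np.array([_logit(p_cci_change)]))
    occ_d = CoefTable(("intercept",), np.array([_logit(p_dci_change)]))
    direction = CoefTable(("intercept",), np.array([_logit(p_increase)]))
    cci = CciChangeParams(occ_c, None, None, cci_size_mode) \
        if cci_size_mode == "fixed_one" else CciChangeParams(
            occ_c,
            CoefTable(("intercept",), np.array([-30.0])),
            CoefTable(("intercept",), np.array([-30.0])),
            cci_size_mode)
    if dci_size_mode == "fixed_grid":
        dci = DciChangeParams(occ_d, direction, None, None, "fixed_grid")
    else:
        unit = GammaSizeParams(
            shape=50.0, mean=CoefTable(("intercept",),
                                       np.array([np.log(DCI_STEP)])))
        dci = DciChangeParams(occ_d, direction, unit, unit, "gamma")
    return TransitionModelSet(death, cci, dci, cat)
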