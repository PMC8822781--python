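"""Annual state-transition microsimulation and life expectancy.

Each simulated man carries a state (age, CCI, DCI, alive).  One annual
cycle applies, in order: a death draw; a CCI-change draw and, on change,
an increment draw; a DCI-change draw with direction and size draws; then
age advances by one year.  Nobody survives beyond age 105.  A cohort of
identical men yields a survival curve (fraction alive at each annual
anniversary), and life expectancy is the trapezoidal area under that
curve — equivalently, half-year credit in the year of death.

Random numbers come from three named, independent sub-streams per cohort
run (``mortality``, ``cci``, ``dci``), keyed by (seed, combination,
stream).  Because the CCI block and the DCI block read start-of-year
covariates and consume disjoint streams, running the DCI block before the
CCI block produces bit-identical output — the algorithm's step order
between the two comorbidity blocks is immaterial, and here that holds
exactly, not just in distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import (
    TransitionModelSet,
    cci_change_probability,
    dci_transition_probabilities,
    death_probability,
    sample_cci_increment,
    sample_dci_step,
)
from .records import AGE_MAX, AGE_MIN, DCI_FLOOR, DCI_STEP, on_dci_grid

__all__ = [
    "IndividualState",
    "SimConfig",
    "SurvivalCurve",
    "CohortPanel",
    "LifeExpectancyTable",
    "OracleResult",
    "make_streams",
    "advance_one_year",
    "simulate_cohort",
    "simulate_panel",
    "life_expectancy",
    "le_standard_error",
    "life_expectancy_grid",
    "exact_survival_oracle",
]

STREAM_NAMES = ("mortality", "cci", "dci")


def _default_dci_grid() -> Tuple[float, ...]:
    return tuple(np.round(np.arange(DCI_FLOOR, 13.5 + DCI_STEP / 2,
                                    DCI_STEP), 2))


@dataclass
class IndividualState:
    """State of one simulated man at one annual step."""

    age: int
    cci: int
    dci: float
    alive: bool = True

    def __post_init__(self) -> None:
        if self.alive and not (AGE_MIN <= self.age <= AGE_MAX):
            raise ValidationError(f"age {self.age} outside legal range")
        if self.cci < 0:
            raise ValidationError("cci must be >= 0")
        if not bool(on_dci_grid(self.dci)):
            raise ValidationError("dci must lie on the 0.25 grid")


@dataclass
class SimConfig:
    """Microsimulation configuration.

    Defaults mirror the study design: 10,000 identical men per start
    state, the start grid ages 65..90 x CCI 0..10 x DCI -0.75..13.5 in
    0.25 steps, and termination at age 105.
    """

    n_individuals: int = 10_000
    max_age: int = AGE_MAX
    start_ages: Sequence[int] = tuple(range(65, 91))
    start_cci: Sequence[int] = tuple(range(0, 11))
    start_dci: Sequence[float] = field(default_factory=_default_dci_grid)
    seed: int = 0
    rng_streams: Tuple[str, ...] = STREAM_NAMES

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if any(a < AGE_MIN or a > AGE_MAX for a in self.start_ages):
            raise ValidationError("start ages outside legal range")
        if any(c < 0 for c in self.start_cci):
            raise ValidationError("start CCI must be >= 0")
        if not np.all(on_dci_grid(np.asarray(self.start_dci, float))):
            raise ValidationError("start DCI values must lie on the grid")
        if tuple(self.rng_streams) != STREAM_NAMES:
            raise ValidationError(f"rng streams must be {STREAM_NAMES}")


@dataclass
class SurvivalCurve:
    """Survival fraction at annual anniversaries from one start state."""

    times: np.ndarray
    survival: np.ndarray
    n: Optional[int] = None
    se: Optional[np.ndarray] = None
    start: Optional[Tuple[int, int, float]] = None  # (age, cci, dci)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.survival = np.asarray(self.survival, dtype=float)
        self.validate()

    def validate(self) -> None:
        s = self.survival
        if len(s) != len(self.times) or len(s) == 0:
            raise ValidationError("times/survival length mismatch")
        if not np.isclose(s[0], 1.0):
            raise ValidationError("survival must start at 1")
        if np.any(np.diff(s) > 1e-12):
            raise ValidationError("survival must be non-increasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValidationError("survival must lie in [0, 1]")

    def at(self, t: int) -> float:
        """Survival at integer time t (0 beyond the end of the curve)."""
        if t < 0:
            raise ValidationError("negative time")
        if t >= len(self.survival):
            return float(self.survival[-1]) if np.isclose(
                self.survival[-1], 0.0) else float("nan")
        return float(self.survival[t])


@dataclass
class CohortPanel:
    """Per-year cohort summaries: survival and mean CCI/DCI among the alive."""

    times: np.ndarray
    survival: np.ndarray
    mean_cci: np.ndarray
    mean_dci: np.ndarray
    sd_cci: np.ndarray
    sd_dci: np.ndarray
    n: int

    @property
    def n_alive(self) -> np.ndarray:
        return np.round(self.survival * self.n).astype(int)

    @property
    def curve(self) -> SurvivalCurve:
        return SurvivalCurve(self.times, self.survival, self.n)


@dataclass
class LifeExpectancyTable:
    """(start age, CCI, DCI) -> expected remaining years, with the config."""

    frame: pd.DataFrame  # columns: age, cci, dci, life_expectancy, se, n, seed
    config: SimConfig

    def lookup(self, age: int, cci: int, dci: float) -> float:
        f = self.frame
        m = (f["age"] == age) & (f["cci"] == cci) & np.isclose(f["dci"], dci)
        if not m.any():
            raise ValidationError(f"no entry for ({age}, {cci}, {dci})")
        return float(f.loc[m, "life_expectancy"].iloc[0])


def make_streams(seed: int, *key: int) -> Dict[str, np.random.Generator]:
    """Three named independent generators keyed by (seed, *key, stream)."""
    return {
        name: np.random.default_rng(
            np.random.SeedSequence([int(seed), *map(int, key), i]))
        for i, name in enumerate(STREAM_NAMES)
    }


def _advance_year_vec(age: np.ndarray, cci: np.ndarray, dci: np.ndarray,
                      models: TransitionModelSet,
                      streams: Dict[str, np.random.Generator],
                      dci_first: bool = False):
    """One annual update for arrays of alive individuals.

    Returns (died, cci_next, dci_next); entries of individuals who died
    keep their start-of-year covariates.  Transition probabilities use
    start-of-year covariates and each block consumes only its own stream,
    which makes the CCI-block/DCI-block order irrelevant bit-for-bit.
    """
    cat = models.categorizer
    n = len(age)
    p_d = death_probability(age, cci.astype(float), dci, models.death)
    died = streams["mortality"].uniform(size=n) < p_d
    surv = np.flatnonzero(~died)
    cci_new = cci.copy()
    dci_new = dci.copy()
    a, c, d = age[surv], cci[surv].astype(float), dci[surv]

    def cci_block() -> None:
        if surv.size == 0:
            return
        p = cci_change_probability(a, c, d, models.cci, cat)
        ch = streams["cci"].uniform(size=surv.size) < p
        if ch.any():
            inc = sample_cci_increment(a[ch], c[ch], d[ch], models.cci, cat,
                                       streams["cci"])
            cci_new[surv[ch]] = cci[surv[ch]] + inc

    def dci_block() -> None:
        if surv.size == 0:
            return
        p_ch, p_inc = dci_transition_probabilities(a, c, d, models.dci, cat)
        ch = streams["dci"].uniform(size=surv.size) < p_ch
        if not ch.any():
            return
        idx = surv[ch]
        up = streams["dci"].uniform(size=idx.size) < p_inc[ch]
        if up.any():
            step = sample_dci_step(a[ch][up], c[ch][up], d[ch][up],
                                   "increase", models.dci, cat,
                                   streams["dci"])
            new = d[ch][up] + step
            dci_new[idx[up]] = np.round(new / DCI_STEP) * DCI_STEP
        dn = ~up
        if dn.any():
            step = sample_dci_step(a[ch][dn], c[ch][dn], d[ch][dn],
                                   "decrease", models.dci, cat,
                                   streams["dci"])
            new = np.maximum(d[ch][dn] - step, DCI_FLOOR)
            dci_new[idx[dn]] = np.round(new / DCI_STEP) * DCI_STEP

    if dci_first:
        dci_block()
        cci_block()
    else:
        cci_block()
        dci_block()
    return died, cci_new, dci_new


def advance_one_year(state: IndividualState, models: TransitionModelSet,
                     streams: Dict[str, np.random.Generator],
                     dci_first: bool = False) -> IndividualState:
    """Apply one annual cycle to a single individual.

    On death the covariates are untouched and age does not advance; on
    survival the (possibly updated) comorbidities carry over and age
    increases by one.
    """
    if not state.alive:
        raise ValidationError("advance_one_year requires a living state")
    died, cci_new, dci_new = _advance_year_vec(
        np.array([float(state.age)]), np.array([state.cci], dtype=np.int64),
        np.array([state.dci], dtype=float), models, streams, dci_first)
    if died[0]:
        return IndividualState(state.age, state.cci, state.dci, alive=False)
    return IndividualState(state.age + 1, int(cci_new[0]),
                           float(dci_new[0]), alive=True)


def _run_cohort(start: IndividualState, models: TransitionModelSet,
                config: SimConfig, comb_key: int, dci_first: bool,
                panel: bool):
    if not start.alive:
        raise ValidationError("start state must be alive")
    n = config.n_individuals
    streams = make_streams(config.seed, comb_key)
    cci = np.full(n, start.cci, dtype=np.int64)
    dci = np.full(n, float(start.dci))
    age = int(start.age)
    survival = [1.0]
    mean_cci = [float(start.cci)]
    mean_dci = [float(start.dci)]
    sd_cci = [0.0]
    sd_dci = [0.0]
    while len(cci) > 0 and age < config.max_age:
        ages = np.full(len(cci), float(age))
        died, cci_new, dci_new = _advance_year_vec(
            ages, cci, dci, models, streams, dci_first)
        keep = ~died
        cci = cci_new[keep]
        dci = dci_new[keep]
        age += 1
        survival.append(len(cci) / n)
        mean_cci.append(float(cci.mean()) if len(cci) else np.nan)
        mean_dci.append(float(dci.mean()) if len(dci) else np.nan)
        sd_cci.append(float(cci.std()) if len(cci) else np.nan)
        sd_dci.append(float(dci.std()) if len(dci) else np.nan)
    if len(cci) > 0:
        # Survivors at max_age count as alive at that anniversary and are
        # then terminated: the curve is forced to zero one step later.
        survival.append(0.0)
        mean_cci.append(np.nan)
        mean_dci.append(np.nan)
        sd_cci.append(np.nan)
        sd_dci.append(np.nan)
    times = np.arange(len(survival))
    s = np.asarray(survival)
    se = np.sqrt(np.clip(s * (1 - s), 0, None) / n)
    curve = SurvivalCurve(times, s, n=n, se=se,
                          start=(start.age, start.cci, start.dci))
    if panel:
        return CohortPanel(times, s, np.asarray(mean_cci),
                           np.asarray(mean_dci), np.asarray(sd_cci),
                           np.asarray(sd_dci), n)
    return curve


def simulate_cohort(start: IndividualState, models: TransitionModelSet,
                    config: SimConfig, comb_key: int = 0,
                    dci_first: bool = False) -> SurvivalCurve:
    """Simulate ``config.n_individuals`` identical men from ``start``."""
    return _run_cohort(start, models, config, comb_key, dci_first,
                       panel=False)


def simulate_panel(start: IndividualState, models: TransitionModelSet,
                   config: SimConfig, comb_key: int = 0) -> CohortPanel:
    """As :func:`simulate_cohort` but also track mean CCI/DCI among the alive."""
    return _run_cohort(start, models, config, comb_key, False, panel=True)


def life_expectancy(curve: SurvivalCurve) -> float:
    """Trapezoidal area under the survival curve, in years."""
    curve.validate()
    return float(np.trapezoid(curve.survival, curve.times))


def le_standard_error(curve: SurvivalCurve) -> float:
    """Monte-Carlo standard error of the life-expectancy estimate.

    Individuals are independent, and with the trapezoid rule each death in
    year t contributes t - 0.5 years, so the SE follows from the death-time
    distribution encoded by the curve.
    """
    if curve.n is None:
        raise ValidationError("curve carries no sample size")
    s = curve.survival
    if not np.isclose(s[-1], 0.0):
        raise ValidationError("curve must reach zero for a lifetime SE")
    p = -np.diff(s)
    x = curve.times[1:] - 0.5
    mean = float(np.sum(p * x))
    var = float(np.sum(p * x ** 2) - mean ** 2)
    return float(np.sqrt(max(var, 0.0) / curve.n))


def life_expectancy_grid(models: TransitionModelSet,
                         config: SimConfig) -> LifeExpectancyTable:
    """One cohort simulation per (start age, CCI, DCI) combination.

    Combinations use independent RNG keys, so they are independent and
    their execution order is immaterial.
    """
    rows = []
    combos = itertools.product(config.start_ages, config.start_cci,
                               config.start_dci)
    for comb_key, (a, c, d) in enumerate(combos):
        curve = simulate_cohort(IndividualState(int(a), int(c), float(d)),
                                models, config, comb_key=comb_key)
        rows.append({
            "age": int(a), "cci": int(c), "dci": float(d),
            "life_expectancy": life_expectancy(curve),
            "se": le_standard_error(curve),
            "n": config.n_individuals, "seed": config.seed,
        })
    return LifeExpectancyTable(pd.DataFrame(rows), config)


@dataclass
class OracleResult:
    """Exact finite-chain survival and state means (no sampling)."""

    times: np.ndarray
    survival: np.ndarray
    mean_cci: np.ndarray
    mean_dci: np.ndarray

    @property
    def curve(self) -> SurvivalCurve:
        return SurvivalCurve(self.times, self.survival)


def exact_survival_oracle(models: TransitionModelSet,
                          start: IndividualState,
                          horizon: int,
                          max_age: int = AGE_MAX) -> OracleResult:
    """Exact forward propagation of the state distribution.

    Requires degenerate size models (CCI increment fixed at 1, DCI step
    fixed at one 0.25 grid unit) so the annual process is a finite Markov
    chain over (age, CCI, DCI).  Serves as a sampling-free cross-check of
    :func:`simulate_cohort`.
    """
    if models.cci.size_mode != "fixed_one" or \
            models.dci.size_mode != "fixed_grid":
        raise ValidationError(
            "exact oracle requires degenerate size models "
            "(cci fixed_one, dci fixed_grid)")
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    cat = models.categorizer
    n_c = horizon + 1
    d0_idx = int(round((start.dci - DCI_FLOOR) / DCI_STEP))
    n_d = d0_idx + horizon + 1
    c_vals = start.cci + np.arange(n_c, dtype=float)
    d_vals = DCI_FLOOR + DCI_STEP * np.arange(n_d)
    C, D = np.meshgrid(c_vals, d_vals, indexing="ij")
    M = np.zeros((n_c, n_d))
    M[0, d0_idx] = 1.0

    survival = [1.0]
    mean_cci = [float(start.cci)]
    mean_dci = [float(start.dci)]
    for t in range(horizon):
        age = start.age + t
        if age >= max_age:
            survival.append(0.0)
            mean_cci.append(np.nan)
            mean_dci.append(np.nan)
            break
        A = np.full_like(C, float(age))
        p_d = death_probability(A, C, D, models.death)
        M = M * (1.0 - p_d)
        p_c = cci_change_probability(A, C, D, models.cci, cat)
        p_ch, p_inc = dci_transition_probabilities(A, C, D, models.dci, cat)
        p_up = p_ch * p_inc
        p_dn = p_ch * (1.0 - p_inc)
        p_sd = 1.0 - p_ch

        def spread_dci(W):
            out = W * p_sd
            out[:, 1:] += (W * p_up)[:, :-1]
            out[:, :-1] += (W * p_dn)[:, 1:]
            out[:, 0] += (W * p_dn)[:, 0]  # decrease at the floor truncates
            return out

        stay_c = spread_dci(M * (1.0 - p_c))
        move_c = spread_dci(M * p_c)
        M = stay_c
        M[1:, :] += move_c[:-1, :]
        mass = M.sum()
        survival.append(float(mass))
        if mass > 0:
            mean_cci.append(float((M * C).sum() / mass))
            mean_dci.append(float((M * D).sum() / mass))
        else:  # pragma: no cover - requires a forced death probability of 1
            mean_cci.append(np.nan)
            mean_dci.append(np.nan)
    return OracleResult(np.arange(len(survival)), np.asarray(survival),
                        np.asarray(mean_cci), np.asarray(mean_dci))
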