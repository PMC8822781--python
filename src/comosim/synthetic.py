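"""Synthetic person-year cohorts with registry structure.

The generator emulates the structure of a population-based comparison
cohort of elderly men: entry ages 65-90, a cumulative (non-decreasing)
CCI, a DCI that can rise and fall on a 0.25 grid from -0.75, six
exchangeable health-care regions, annual emigration-style censoring and
administrative censoring after at most 11 years of follow-up.  Cohorts
evolve under a known ground-truth :class:`TransitionModelSet` using the
same annual update engine as the microsimulation, which makes round-trip
parameter recovery (fit the models on a generated cohort, compare with
the truth) the module's central testable guarantee.

The default entry distributions reproduce the qualitative age gradient of
such cohorts — the share of men with CCI = 0 falls from about 80% at age
65 toward about 45% at 90, and the share with DCI > 0 rises from about
70% to about 85% — without targeting any registry's exact marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .microsim import _advance_year_vec, SurvivalCurve, make_streams
from .models import (
    CciChangeParams,
    CoefTable,
    CovariateCategorizer,
    DciChangeParams,
    DeathModelParams,
    GammaSizeParams,
    TransitionModelSet,
)
from .records import AGE_MAX, COLUMNS, DCI_FLOOR, DCI_STEP

__all__ = [
    "SyntheticCohortSpec",
    "default_truth",
    "default_spec",
    "generate_cohort",
    "summarize_entry_distributions",
    "simulate_entry_states",
    "ENTRY_AGES",
    "ENTRY_DCI_VALUES",
]

ENTRY_AGES = np.arange(65, 91)
ENTRY_CCI_VALUES = np.arange(0, 11)
ENTRY_DCI_VALUES = np.round(np.arange(DCI_FLOOR, 6.0 + DCI_STEP / 2,
                                      DCI_STEP), 2)

_OCC_NAMES = ("intercept", "age_1", "age_2", "cci_1", "cci_2", "cci_3",
              "dci_1", "dci_2", "dci_3")
# In the CCI = 0 stratum the CCI dummies are void; in the CCI > 0 stratum
# the category-3 dummy is absorbed (intercept = CCI >= 3 baseline).
_SIZE0_NAMES = ("intercept", "age_1", "age_2", "dci_1", "dci_2", "dci_3")
_SIZE1_NAMES = ("intercept", "age_1", "age_2", "cci_1", "cci_2",
                "dci_1", "dci_2", "dci_3")


def default_truth() -> TransitionModelSet:
    """A realistic ground-truth model set for elderly-male cohorts.

    Annual mortality is about 1.3% at (age 65, CCI 0, DCI 0) and about
    13% at age 90, rising with both comorbidity indices with an effect
    that attenuates at high ages (the age-100 QCS interaction).  CCI
    events hit roughly 6-15% of person-years; DCI changes are common
    (about 35-55% of person-years) with mean step sizes below one unit.
    """
    death = DeathModelParams(
        intercept=-6.40, beta_age=0.0575,
        beta_cci=-0.004, beta_dci=-0.002,
        gamma_cci=-6e-6, gamma_dci=-3e-6,
    )
    cci = CciChangeParams(
        occurrence=CoefTable(_OCC_NAMES, np.array(
            [-2.75, 0.35, 0.70, 0.30, 0.50, 0.70, 0.20, 0.40, 0.60])),
        size_stratum0=CoefTable(_SIZE0_NAMES, np.array(
            [-1.386, 0.10, 0.20, 0.05, 0.10, 0.15])),
        size_stratum1=CoefTable(_SIZE1_NAMES, np.array(
            [-0.916, 0.10, 0.20, -0.20, -0.10, 0.05, 0.10, 0.15])),
        size_mode="poisson",
    )
    dci = DciChangeParams(
        occurrence=CoefTable(_OCC_NAMES, np.array(
            [-0.62, 0.10, 0.20, 0.10, 0.15, 0.20, 0.30, 0.50, 0.70])),
        direction=CoefTable(_OCC_NAMES, np.array(
            [0.405, 0.05, 0.10, 0.05, 0.08, 0.10, -0.30, -0.60, -0.90])),
        increase=GammaSizeParams(shape=2.0, mean=CoefTable(_OCC_NAMES,
            np.array([-0.105, 0.05, 0.10, 0.03, 0.05, 0.08,
                      0.10, 0.20, 0.30]))),
        decrease=GammaSizeParams(shape=2.0, mean=CoefTable(_OCC_NAMES,
            np.array([-0.511, 0.05, 0.10, 0.02, 0.04, 0.06,
                      0.10, 0.30, 0.50]))),
        size_mode="gamma",
    )
    return TransitionModelSet(death, cci, dci, CovariateCategorizer())


def random_degenerate_models(rng: np.random.Generator
                             ) -> TransitionModelSet:
    """A random model set with degenerate change sizes (CCI +1, DCI one
    grid unit), suitable for exact finite-chain oracle cross-checks.

    Mortality is anchored at a moderate level (5-15% per year at age 75)
    so Monte-Carlo and exact survival are compared away from the 0/1
    boundaries; occurrence and direction models carry random category
    effects to exercise the categorised designs.
    """
    from scipy.special import logit

    from .models import death_probability

    cat = CovariateCategorizer()

    def random_coefs(p_lo: float, p_hi: float, spread: float) -> CoefTable:
        vals = rng.normal(0.0, spread, len(_OCC_NAMES))
        vals[0] = logit(rng.uniform(p_lo, p_hi))
        return CoefTable(_OCC_NAMES, vals)

    death = DeathModelParams(
        intercept=0.0,
        beta_age=rng.uniform(0.0, 0.02),
        beta_cci=-rng.uniform(0.0, 2e-3),
        beta_dci=-rng.uniform(0.0, 1e-3),
        gamma_cci=-rng.uniform(0.0, 1e-6),
        gamma_dci=-rng.uniform(0.0, 5e-7),
    )
    q75 = rng.uniform(0.05, 0.15)
    eta0 = float(np.log(death_probability(75, 1, 0.5, death)
                        / (1 - death_probability(75, 1, 0.5, death))))
    death.intercept = float(logit(q75)) - eta0
    cci = CciChangeParams(random_coefs(0.1, 0.4, 0.3), None, None,
                          "fixed_one")
    dci = DciChangeParams(random_coefs(0.2, 0.5, 0.3),
                          random_coefs(0.35, 0.65, 0.3),
                          None, None, "fixed_grid")
    return TransitionModelSet(death, cci, dci, cat)


def _default_age_weights() -> np.ndarray:
    w = np.exp(-0.06 * (ENTRY_AGES - 65))
    return w / w.sum()


def _default_cci_weights() -> np.ndarray:
    """Age-shifted entry CCI: P(CCI=0) falls from ~0.80 at 65 to ~0.45 at 90."""
    out = np.zeros((len(ENTRY_AGES), len(ENTRY_CCI_VALUES)))
    tail = 0.55 ** np.arange(10)
    tail = tail / tail.sum()
    for i, age in enumerate(ENTRY_AGES):
        p0 = 0.80 - 0.35 * (age - 65) / 25.0
        out[i, 0] = p0
        out[i, 1:] = (1 - p0) * tail
    return out


def _default_dci_weights() -> np.ndarray:
    """Age-shifted entry DCI: P(DCI>0) rises from ~0.70 at 65 to ~0.85 at 90."""
    nonpos = np.array([0.10, 0.15, 0.25, 0.50])  # -0.75, -0.5, -0.25, 0
    pos_vals = ENTRY_DCI_VALUES[4:]
    pos = np.exp(-pos_vals / 1.25)
    out = np.zeros((len(ENTRY_AGES), len(ENTRY_DCI_VALUES)))
    for i, age in enumerate(ENTRY_AGES):
        p_np = 0.30 - 0.15 * (age - 65) / 25.0
        out[i, :4] = p_np * nonpos / nonpos.sum()
        out[i, 4:] = (1 - p_np) * pos / pos.sum()
    return out


@dataclass
class SyntheticCohortSpec:
    """Everything needed to generate one synthetic person-year cohort."""

    n_individuals: int
    truth: TransitionModelSet
    seed: int
    entry_age_weights: np.ndarray = field(
        default_factory=_default_age_weights)
    entry_cci_weights: np.ndarray = field(
        default_factory=_default_cci_weights)  # (n_ages, 11), rows per age
    entry_dci_weights: np.ndarray = field(
        default_factory=_default_dci_weights)  # (n_ages, n_grid)
    n_regions: int = 6
    max_followup: int = 11
    annual_censor_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if self.max_followup < 1:
            raise ValidationError("max_followup must be >= 1")
        if not 0.0 <= self.annual_censor_prob <= 1.0:
            raise ValidationError("annual_censor_prob must be in [0, 1]")
        for name, w, shape in (
                ("entry_age_weights", self.entry_age_weights,
                 (len(ENTRY_AGES),)),
                ("entry_cci_weights", self.entry_cci_weights,
                 (len(ENTRY_AGES), len(ENTRY_CCI_VALUES))),
                ("entry_dci_weights", self.entry_dci_weights,
                 (len(ENTRY_AGES), len(ENTRY_DCI_VALUES)))):
            arr = np.asarray(w, dtype=float)
            if arr.shape != shape:
                raise ValidationError(f"{name} must have shape {shape}")
            if np.any(arr < 0) or np.any(arr.sum(axis=-1) <= 0):
                raise ValidationError(f"{name} must be non-negative weights")
            sums = arr.sum(axis=-1, keepdims=True)
            setattr(self, name, arr / sums)


def default_spec(n_individuals: int, seed: int,
                 truth: Optional[TransitionModelSet] = None,
                 **overrides) -> SyntheticCohortSpec:
    return SyntheticCohortSpec(n_individuals=n_individuals,
                               truth=truth or default_truth(),
                               seed=seed, **overrides)


def _sample_by_age(rng: np.random.Generator, age_idx: np.ndarray,
                   weights: np.ndarray, values: np.ndarray) -> np.ndarray:
    out = np.empty(len(age_idx), dtype=float)
    for i in np.unique(age_idx):
        m = age_idx == i
        out[m] = rng.choice(values, size=int(m.sum()), p=weights[i])
    return out


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Generate one long-format person-year cohort under ``spec.truth``.

    Each individual enters with a drawn (region, age, CCI, DCI), evolves
    annually under the ground-truth transition models via the shared
    microsimulation engine, and stops at death, censoring (emigration
    surrogate or the administrative follow-up cap), or age 105.  One
    record is emitted per observed year; next-year covariates are absent
    in death/censoring years.
    """
    n = spec.n_individuals
    rng_entry = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 9001]))
    rng_censor = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 9002]))
    streams = make_streams(spec.seed, 7)

    age_idx = rng_entry.choice(len(ENTRY_AGES), size=n,
                               p=spec.entry_age_weights)
    age = ENTRY_AGES[age_idx].astype(np.int64)
    cci = _sample_by_age(rng_entry, age_idx, spec.entry_cci_weights,
                         ENTRY_CCI_VALUES.astype(float)).astype(np.int64)
    dci = _sample_by_age(rng_entry, age_idx, spec.entry_dci_weights,
                         ENTRY_DCI_VALUES)
    region = rng_entry.integers(1, spec.n_regions + 1, size=n)

    ids = np.arange(n, dtype=np.int64)
    chunks = []
    for t in range(spec.max_followup):
        m = len(ids)
        if m == 0:
            break
        died, cci_nx, dci_nx = _advance_year_vec(
            age.astype(float), cci, dci, spec.truth, streams)
        censor_u = rng_censor.uniform(size=m)
        admin = (t == spec.max_followup - 1) | (age + 1 >= AGE_MAX)
        censored = ~died & ((censor_u < spec.annual_censor_prob) | admin)
        completed = ~died & ~censored
        chunks.append(pd.DataFrame({
            "person_id": ids,
            "region": region[ids],
            "year_index": t,
            "age": age,
            "cci": cci,
            "dci": dci,
            "died": died.astype(np.int64),
            "censored": censored.astype(np.int64),
            "cci_next": np.where(completed, cci_nx.astype(float), np.nan),
            "dci_next": np.where(completed, dci_nx, np.nan),
        }))
        ids = ids[completed]
        age = age[completed] + 1
        cci = cci_nx[completed]
        dci = dci_nx[completed]
    out = pd.concat(chunks, ignore_index=True)
    out = out.sort_values(["person_id", "year_index"], ignore_index=True)
    return out[list(COLUMNS)]


def summarize_entry_distributions(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-entry-age prevalence of CCI = 0 and DCI > 0 among entrants."""
    entry = cohort[cohort["year_index"] == 0]
    if len(entry) == 0:
        raise ValidationError("cohort has no entry rows")
    g = entry.groupby("age")
    return pd.DataFrame({
        "n": g.size(),
        "prevalence_cci0": g.apply(
            lambda s: float((s["cci"] == 0).mean()), include_groups=False),
        "prevalence_dci_pos": g.apply(
            lambda s: float((s["dci"] > 0).mean()), include_groups=False),
    })


def simulate_entry_states(ages: Sequence[int], ccis: Sequence[int],
                          dcis: Sequence[float],
                          models: TransitionModelSet,
                          n_years: int, seed: int,
                          replicates: int = 1,
                          return_panel: bool = False):
    """Simulate a mixed cohort started from given per-individual states.

    Each supplied entry state is replicated ``replicates`` times and run
    for ``n_years`` under ``models`` with no censoring; returns the
    survival curve of the mixture (used for held-out-region validation),
    or a :class:`CohortPanel` with per-year mean CCI/DCI when
    ``return_panel`` is set.
    """
    from .microsim import CohortPanel

    age = np.repeat(np.asarray(ages, dtype=np.int64), replicates)
    cci = np.repeat(np.asarray(ccis, dtype=np.int64), replicates)
    dci = np.repeat(np.asarray(dcis, dtype=float), replicates)
    n = len(age)
    if n == 0:
        raise ValidationError("no entry states supplied")
    streams = make_streams(seed, 11)
    survival = [1.0]
    mean_cci = [float(cci.mean())]
    mean_dci = [float(dci.mean())]
    sd_cci = [float(cci.std())]
    sd_dci = [float(dci.std())]
    for t in range(n_years):
        if len(age) == 0:
            survival.append(survival[-1])
            for track in (mean_cci, mean_dci, sd_cci, sd_dci):
                track.append(np.nan)
            continue
        died, cci_nx, dci_nx = _advance_year_vec(
            age.astype(float), cci, dci, models, streams)
        n_prior_dead = n - len(age)
        survival.append((n - n_prior_dead - int(died.sum())) / n)
        # Individuals reaching the age cap count as alive at this
        # anniversary and are then terminated.
        keep = ~died & (age + 1 < AGE_MAX)
        age = age[keep] + 1
        cci = cci_nx[keep]
        dci = dci_nx[keep]
        mean_cci.append(float(cci.mean()) if len(cci) else np.nan)
        mean_dci.append(float(dci.mean()) if len(dci) else np.nan)
        sd_cci.append(float(cci.std()) if len(cci) else np.nan)
        sd_dci.append(float(dci.std()) if len(dci) else np.nan)
    s = np.asarray(survival)
    se = np.sqrt(np.clip(s * (1 - s), 0, None) / n)
    times = np.arange(len(s))
    if return_panel:
        return CohortPanel(times, s, np.asarray(mean_cci),
                           np.asarray(mean_dci), np.asarray(sd_cci),
                           np.asarray(sd_dci), n)
    return SurvivalCurve(times, s, n=n, se=se)
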