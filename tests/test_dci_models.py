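import numpy as np
import pandas as pd
import pytest

import comosim as cs
from comosim.models import CoefTable, DciChangeParams, GammaSizeParams


def make_params(occ, direction, mean_inc=0.0, mean_dec=0.0, shape=2.0):
    return DciChangeParams(
        occurrence=CoefTable.from_dict(occ),
        direction=CoefTable.from_dict(direction),
        increase=GammaSizeParams(shape, CoefTable.from_dict(
            {"intercept": mean_inc})),
        decrease=GammaSizeParams(shape, CoefTable.from_dict(
            {"intercept": mean_dec})))


def test_zero_coefficients_give_half_half(categorizer):
    p = make_params({"intercept": 0.0}, {"intercept": 0.0})
    assert cs.dci_transition_probabilities(70, 0, 0.0, p, categorizer) == \
        (0.5, 0.5)


def test_hand_computed_pair(categorizer):
    p = make_params({"intercept": -0.5, "dci_2": 0.4},
                    {"intercept": 0.3, "age_2": -0.2})
    # age 88 -> age_2; dci 2.0 -> dci_2
    pc, pi = cs.dci_transition_probabilities(88, 0, 2.0, p, categorizer)
    assert pc == pytest.approx(1 / (1 + np.exp(0.5 - 0.4)), rel=1e-12)
    assert pi == pytest.approx(1 / (1 + np.exp(-0.3 + 0.2)), rel=1e-12)
    assert 0 < pc < 1 and 0 < pi < 1


def test_steps_live_on_grid(categorizer):
    p = make_params({"intercept": 0.0}, {"intercept": 0.0},
                    mean_inc=np.log(0.8), mean_dec=np.log(0.8))
    rng = np.random.default_rng(7)
    steps = cs.sample_dci_step(np.full(5000, 70.0), np.zeros(5000),
                               np.full(5000, 5.0), "increase", p,
                               categorizer, rng)
    k = steps / 0.25
    assert np.allclose(k, np.round(k))
    assert steps.min() >= 0.25


def test_decrease_truncated_at_floor(categorizer):
    p = make_params({"intercept": 0.0}, {"intercept": 0.0},
                    mean_dec=np.log(3.0))
    rng = np.random.default_rng(8)
    # at the floor the step truncates to exactly 0
    step = cs.sample_dci_step(70, 0, -0.75, "decrease", p, categorizer, rng)
    assert step == 0.0
    steps = cs.sample_dci_step(np.full(2000, 70.0), np.zeros(2000),
                               np.full(2000, 0.5), "decrease", p,
                               categorizer, rng)
    assert steps.max() <= 0.5 - (-0.75) + 1e-12
    assert np.all(steps >= 0.0)


def test_step_mean_close_to_gamma_mean(categorizer):
    """Rounding perturbs the mean by at most ~a quarter grid unit."""
    mu = 2.0
    p = make_params({"intercept": 0.0}, {"intercept": 0.0},
                    mean_inc=np.log(mu))
    rng = np.random.default_rng(9)
    n = 100_000
    steps = cs.sample_dci_step(np.full(n, 70.0), np.zeros(n),
                               np.full(n, 5.0), "increase", p,
                               categorizer, rng)
    se = steps.std() / np.sqrt(n)
    assert abs(steps.mean() - mu) < 4 * se + 0.13


def _dci_table(rng, n=6000, p_change=0.5, p_inc=0.5):
    age = rng.integers(65, 91, n)
    cci = rng.integers(0, 5, n)
    dci = rng.choice([2.0, 2.5, 3.5, 5.0], n)  # far from the floor
    change = rng.uniform(size=n) < p_change
    up = rng.uniform(size=n) < p_inc
    step = np.maximum(0.25, np.round(rng.gamma(2.0, 0.25, n) / 0.25) * 0.25)
    delta = np.where(change, np.where(up, step, -step), 0.0)
    return pd.DataFrame({
        "person_id": np.arange(n), "region": 1, "year_index": 0,
        "age": age, "cci": cci, "dci": dci, "died": 0, "censored": 0,
        "cci_next": cci.astype(float), "dci_next": dci + delta,
    })


def test_fit_errors_on_constant_dci(categorizer):
    rng = np.random.default_rng(10)
    table = _dci_table(rng, p_change=0.0)
    with pytest.raises(cs.DegenerateFitError):
        cs.fit_dci_models(table, categorizer)


def test_fit_errors_on_missing_direction(categorizer):
    rng = np.random.default_rng(11)
    table = _dci_table(rng, p_inc=1.0)
    with pytest.raises((cs.StratumError, cs.DegenerateFitError)):
        cs.fit_dci_models(table, categorizer)


def test_direction_relabel_flips_coefficients(categorizer):
    """Mirroring every change (increase <-> decrease) negates the
    direction model's coefficients and swaps the size models."""
    rng = np.random.default_rng(12)
    table = _dci_table(rng, p_inc=0.6)
    mirrored = table.copy()
    mirrored["dci_next"] = 2 * mirrored["dci"] - mirrored["dci_next"]
    a = cs.fit_dci_models(table, categorizer)
    b = cs.fit_dci_models(mirrored, categorizer)
    assert a.direction.names == b.direction.names
    assert np.allclose(a.direction.values, -b.direction.values, atol=1e-5)
    assert np.allclose(a.occurrence.values, b.occurrence.values, atol=1e-5)
    assert a.increase.shape == pytest.approx(b.decrease.shape, rel=1e-3)


def test_round_trip_recovery_on_small_cohort(truth, fitted_models):
    est = fitted_models.dci
    for name, tru in (("occurrence", truth.dci.occurrence),
                      ("direction", truth.dci.direction)):
        got = getattr(est, name)
        assert got.names == tru.names
        z = (got.values - tru.values) / got.bse
        assert np.all(np.abs(z) < 4), (name, z)
    for name in ("increase", "decrease"):
        got = getattr(est, name)
        tru = getattr(truth.dci, name)
        z = (got.mean.values - tru.mean.values) / got.mean.bse
        assert np.all(np.abs(z) < 4), (name, z)
        zs = (np.log(got.shape) - np.log(tru.shape)) / got.log_shape_bse
        assert abs(zs) < 4
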