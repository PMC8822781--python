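import numpy as np
import pandas as pd
import pytest

import comosim as cs
from comosim.models import CciChangeParams, CoefTable


def make_params(occ, size0, size1):
    return CciChangeParams(
        occurrence=CoefTable.from_dict(occ),
        size_stratum0=CoefTable.from_dict(size0),
        size_stratum1=CoefTable.from_dict(size1))


def test_categorizer_codes(categorizer):
    assert list(categorizer.cci_code([0, 1, 2, 3, 10])) == [0, 1, 2, 3, 3]
    assert list(categorizer.dci_code([-0.75, 0.0, 0.25, 1.0, 1.25, 3.0,
                                      3.25])) == [0, 0, 1, 1, 2, 2, 3]
    assert list(categorizer.age_code([65, 74, 75, 84, 85, 100])) == \
        [0, 0, 1, 1, 2, 2]


def test_zero_coefficients_give_half(categorizer):
    p = make_params({"intercept": 0.0}, {"intercept": 0.0},
                    {"intercept": 0.0})
    assert cs.cci_change_probability(70, 1, 0.5, p, categorizer) == 0.5


def test_same_category_same_probability(categorizer):
    p = make_params(
        {"intercept": -2.0, "age_1": 0.4, "cci_3": 0.6, "dci_2": 0.3},
        {"intercept": -1.0}, {"intercept": -1.0})
    # (age 76, cci 4, dci 2.0) and (age 84, cci 9, dci 1.5) share all bins
    a = cs.cci_change_probability(76, 4, 2.0, p, categorizer)
    b = cs.cci_change_probability(84, 9, 1.5, p, categorizer)
    assert a == b


def test_hand_computed_probability(categorizer):
    p = make_params(
        {"intercept": -2.0, "age_1": 0.4, "cci_1": 0.2, "dci_1": 0.1},
        {"intercept": -1.0}, {"intercept": -1.0})
    # age 78 -> age_1; cci 1 -> cci_1; dci 0.5 -> dci_1
    eta = -2.0 + 0.4 + 0.2 + 0.1
    assert cs.cci_change_probability(78, 1, 0.5, p, categorizer) == \
        pytest.approx(1 / (1 + np.exp(-eta)), rel=1e-12)


def test_increment_support_and_mean(categorizer):
    p = make_params({"intercept": 0.0},
                    {"intercept": np.log(0.7)},
                    {"intercept": np.log(1.4)})
    rng = np.random.default_rng(5)
    n = 200_000
    draws0 = cs.sample_cci_increment(np.full(n, 70.0), np.zeros(n),
                                     np.zeros(n), p, categorizer, rng)
    draws1 = cs.sample_cci_increment(np.full(n, 70.0), np.full(n, 4.0),
                                     np.zeros(n), p, categorizer, rng)
    assert draws0.min() >= 1 and draws1.min() >= 1
    for draws, mean in ((draws0, 1 + 0.7), (draws1, 1 + 1.4)):
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - mean) < 4 * se


def test_degenerate_tiny_mean_returns_one(categorizer):
    p = make_params({"intercept": 0.0}, {"intercept": -30.0},
                    {"intercept": -30.0})
    rng = np.random.default_rng(0)
    draws = cs.sample_cci_increment(np.full(1000, 70.0), np.zeros(1000),
                                    np.zeros(1000), p, categorizer, rng)
    assert np.all(draws == 1)


def _toy_table(rng, n=4000, p_change=0.3, extra_sizes=True):
    age = rng.integers(65, 91, n)
    cci = rng.integers(0, 6, n)
    dci = rng.choice([0.0, 0.5, 1.5, 4.0], n)
    change = rng.uniform(size=n) < p_change
    size = np.where(extra_sizes, 1 + rng.poisson(0.4, n), 1)
    cci_next = np.where(change, cci + size, cci).astype(float)
    return pd.DataFrame({
        "person_id": np.arange(n), "region": 1, "year_index": 0,
        "age": age, "cci": cci, "dci": dci,
        "died": 0, "censored": 0,
        "cci_next": cci_next, "dci_next": dci,
    })


def test_fit_errors_when_no_changes(categorizer):
    rng = np.random.default_rng(1)
    table = _toy_table(rng, p_change=0.0)
    with pytest.raises(cs.DegenerateFitError):
        cs.fit_cci_models(table, categorizer)


def test_fit_all_sizes_one_flags_boundary(categorizer):
    rng = np.random.default_rng(2)
    table = _toy_table(rng, extra_sizes=False)
    with pytest.warns(RuntimeWarning, match="all change sizes are 1"):
        fit = cs.fit_cci_models(table, categorizer)
    mean0 = np.exp(fit.size_stratum0.values[
        list(fit.size_stratum0.names).index("intercept")])
    assert mean0 < 1e-8


def test_fit_empty_stratum_errors(categorizer):
    rng = np.random.default_rng(3)
    table = _toy_table(rng)
    # remove every change among CCI = 0 rows -> stratum-0 estimation error
    m = (table["cci"] == 0)
    table.loc[m, "cci_next"] = table.loc[m, "cci"].astype(float)
    if (table["cci_next"] > table["cci"]).sum() == 0:  # pragma: no cover
        pytest.skip("toy table lost all changes")
    with pytest.raises(cs.StratumError):
        cs.fit_cci_models(table, categorizer)


def test_round_trip_recovery_on_small_cohort(truth, fitted_models):
    """fit(generate(truth)) recovers CCI coefficients within 4 SE."""
    est = fitted_models.cci
    for name, tru in (("occurrence", truth.cci.occurrence),
                      ("size_stratum0", truth.cci.size_stratum0),
                      ("size_stratum1", truth.cci.size_stratum1)):
        got = getattr(est, name)
        assert got.names == tru.names
        z = (got.values - tru.values) / got.bse
        assert np.all(np.abs(z) < 4), (name, z)
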