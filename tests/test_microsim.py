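import numpy as np
import pytest

import comosim as cs


def test_forced_death_short_circuits():
    m = cs.constant_models(1.0, p_cci_change=1.0, p_dci_change=1.0)
    streams = cs.make_streams(0, 1)
    out = cs.advance_one_year(cs.IndividualState(70, 2, 1.0), m, streams)
    assert not out.alive
    assert (out.age, out.cci, out.dci) == (70, 2, 1.0)


def test_no_events_only_ages():
    m = cs.constant_models(0.0)
    streams = cs.make_streams(0, 2)
    out = cs.advance_one_year(cs.IndividualState(70, 2, 1.0), m, streams)
    assert out.alive and (out.age, out.cci, out.dci) == (71, 2, 1.0)


def test_dead_input_rejected():
    m = cs.constant_models(0.1)
    with pytest.raises(cs.ValidationError):
        cs.advance_one_year(cs.IndividualState(70, 0, 0.0, alive=False),
                            m, cs.make_streams(0, 3))


def test_block_order_invariance_single_steps(truth):
    for i in range(100):
        rng = np.random.default_rng(1000 + i)
        state = cs.IndividualState(int(rng.integers(65, 100)),
                                   int(rng.integers(0, 9)),
                                   float(rng.integers(0, 20) * 0.25 - 0.75))
        a = cs.advance_one_year(state, truth, cs.make_streams(42, i),
                                dci_first=False)
        b = cs.advance_one_year(state, truth, cs.make_streams(42, i),
                                dci_first=True)
        assert a == b


def test_simulate_determinism_and_curve_invariants(truth):
    cfg = cs.SimConfig(n_individuals=2000, seed=99)
    start = cs.IndividualState(80, 2, 1.0)
    c1 = cs.simulate_cohort(start, truth, cfg)
    c2 = cs.simulate_cohort(start, truth, cfg)
    assert np.array_equal(c1.survival, c2.survival)
    assert c1.survival[0] == 1.0
    assert np.all(np.diff(c1.survival) <= 0)
    assert np.isclose(c1.survival[-1], 0.0)
    assert len(c1.survival) - 1 <= 105 - 80 + 1


def test_geometric_closed_form():
    q = 0.2
    m = cs.constant_models(q)
    cfg = cs.SimConfig(n_individuals=10_000, seed=7)
    curve = cs.simulate_cohort(cs.IndividualState(65, 0, 0.0), m, cfg)
    for t in range(1, 11):
        s = 0.8 ** t
        tol = 3 * np.sqrt(s * (1 - s) / 10_000)
        assert abs(curve.survival[t] - s) < tol
    le = cs.life_expectancy(curve)
    closed = 0.5 + sum(0.8 ** t for t in range(1, 41))
    assert abs(le - closed) < 3 * cs.le_standard_error(curve)


@pytest.mark.parametrize("survival, expected", [
    ([1.0, 0.0], 0.5),
    ([1.0, 1.0, 0.0], 1.5),
    ([1.0, 0.5, 0.25, 0.0], 1.25),
])
def test_life_expectancy_trapezoid(survival, expected):
    curve = cs.SurvivalCurve(np.arange(len(survival)), survival, n=10)
    assert cs.life_expectancy(curve) == expected


def test_invalid_curve_rejected():
    with pytest.raises(cs.ValidationError):
        cs.SurvivalCurve(np.arange(3), [1.0, 0.5, 0.7])
    with pytest.raises(cs.ValidationError):
        cs.SurvivalCurve(np.arange(2), [0.9, 0.5])


def test_grid_cardinality_and_bounds(truth):
    cfg = cs.SimConfig(n_individuals=200, seed=3, start_ages=(80, 90),
                       start_cci=(0, 4), start_dci=(0.0, 2.0))
    table = cs.life_expectancy_grid(truth, cfg)
    assert len(table.frame) == 8
    le = table.frame["life_expectancy"]
    assert np.all(le >= 0)
    assert np.all(le.to_numpy() <=
                  105 - table.frame["age"].to_numpy() + 1)
    # default configuration instantiates the full start grid
    default = cs.SimConfig(seed=0)
    assert (len(default.start_ages), len(default.start_cci),
            len(default.start_dci)) == (26, 11, 58)


def test_start_at_age_cap_yields_at_most_one_year(truth):
    cfg = cs.SimConfig(n_individuals=100, seed=5, start_ages=(105,),
                       start_cci=(0,), start_dci=(0.0,))
    table = cs.life_expectancy_grid(truth, cfg)
    assert table.frame["life_expectancy"].iloc[0] <= 1.0


def test_oracle_constant_hazard_exact():
    q = 0.3
    m = cs.constant_models(q)
    res = cs.exact_survival_oracle(m, cs.IndividualState(65, 0, 0.0), 10)
    assert np.allclose(res.survival, (1 - q) ** np.arange(11))


def test_oracle_rejects_non_degenerate(truth):
    with pytest.raises(cs.ValidationError):
        cs.exact_survival_oracle(truth, cs.IndividualState(65, 0, 0.0), 5)


def test_oracle_deterministic_cci_drift():
    m = cs.constant_models(0.0, p_cci_change=1.0, p_dci_change=0.0)
    res = cs.exact_survival_oracle(m, cs.IndividualState(65, 2, 0.0), 8)
    assert np.allclose(res.mean_cci, 2 + np.arange(9))
    assert np.allclose(res.mean_dci, 0.0)


def test_oracle_matches_simulation():
    m = cs.constant_models(0.1, p_cci_change=0.3, p_dci_change=0.4,
                           p_increase=0.6)
    start = cs.IndividualState(70, 1, 0.5)
    horizon = 15
    res = cs.exact_survival_oracle(m, start, horizon)
    cfg = cs.SimConfig(n_individuals=10_000, seed=21)
    sim = cs.simulate_cohort(start, m, cfg)
    for t in range(horizon + 1):
        s = res.survival[t]
        tol = 3 * np.sqrt(max(s * (1 - s), 1e-12) / 10_000) + 1e-9
        assert abs(sim.survival[t] - s) < tol
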