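import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import comosim as cs


def _mini_cohort(durations, events, region=1):
    """Cohort with given per-person follow-up lengths and death flags."""
    rows = []
    for pid, (dur, ev) in enumerate(zip(durations, events)):
        for t in range(dur):
            last = t == dur - 1
            rows.append({
                "person_id": pid, "region": region, "year_index": t,
                "age": 70 + t, "cci": 0, "dci": 0.0,
                "died": int(ev and last),
                "censored": int((not ev) and last),
                "cci_next": np.nan if last else 0.0,
                "dci_next": np.nan if last else 0.0,
            })
    return pd.DataFrame(rows)


def test_km_equals_empirical_without_censoring():
    # 4 people: deaths in years 1, 2, 2 and one surviving to year 3 death
    cohort = _mini_cohort([1, 2, 2, 3], [1, 1, 1, 1])
    curve = cs.observed_survival(cohort)
    assert np.allclose(curve.survival, [1.0, 0.75, 0.25, 0.0])


def test_km_all_censored_at_year_one():
    cohort = _mini_cohort([1, 1, 1], [0, 0, 0])
    curve = cs.observed_survival(cohort)
    assert np.allclose(curve.survival, [1.0, 1.0])


def test_empty_stratum_errors(small_cohort):
    with pytest.raises(cs.ValidationError):
        cs.observed_survival(small_cohort, {"age": 200})
    with pytest.raises(cs.ValidationError):
        cs.observed_survival(small_cohort, {"weight": 80})


def test_years_lost_examples():
    flat = cs.SurvivalCurve(np.arange(11), np.ones(11))
    assert cs.years_lost(flat, 10) == 0.0
    drop = cs.SurvivalCurve(np.arange(11),
                            np.concatenate([[1.0], np.zeros(10)]))
    assert cs.years_lost(drop, 10) == 9.5


def test_years_lost_geometric_closed_form():
    q = 0.2
    s = 0.8 ** np.arange(11)
    curve = cs.SurvivalCurve(np.arange(11), s)
    expected = 10 - (0.5 + sum(0.8 ** t for t in range(1, 10))
                     + 0.5 * 0.8 ** 10)
    assert cs.years_lost(curve, 10) == pytest.approx(expected, rel=1e-12)


@given(st.lists(st.floats(0.0, 1.0), min_size=10, max_size=10))
def test_years_lost_conservation(drops):
    """years_lost + area under the curve = horizon, for any curve."""
    s = np.concatenate([[1.0], 1.0 - np.sort(np.asarray(drops))])
    curve = cs.SurvivalCurve(np.arange(11), s)
    area = np.trapezoid(s, np.arange(11))
    assert cs.years_lost(curve, 10) + area == pytest.approx(10.0)


def test_comparison_symmetry():
    a = cs.SurvivalCurve(np.arange(11), 0.9 ** np.arange(11))
    b = cs.SurvivalCurve(np.arange(11), 0.8 ** np.arange(11))
    ab = cs.compare_survival(a, b, 10)
    ba = cs.compare_survival(b, a, 10)
    assert np.allclose(ab.diff, -ba.diff)
    assert ab.max_abs_diff == ba.max_abs_diff
    assert ab.years_lost_difference == -ba.years_lost_difference


def test_calibration_well_calibrated_predictions():
    rng = np.random.default_rng(30)
    p = rng.uniform(0.02, 0.6, 20_000)
    y = (rng.uniform(size=p.size) < p).astype(float)
    table = cs.calibration(p, y, n_bins=10).frame
    assert len(table) == 10
    assert int(table["n"].sum()) == 20_000
    for _, row in table.iterrows():
        bound = 3 * np.sqrt(row["mean_predicted"]
                            * (1 - row["mean_predicted"]) / row["n"])
        assert abs(row["frac_observed"] - row["mean_predicted"]) < bound


def test_calibration_constant_prediction_single_bin():
    with pytest.warns(RuntimeWarning, match="distinct bins"):
        table = cs.calibration(np.full(50, 0.5), np.ones(50), 10)
    assert len(table.frame) == 1
    assert table.frame["frac_observed"].iloc[0] == 1.0
    assert table.frame["mean_predicted"].iloc[0] == 0.5


def test_calibration_invalid_inputs():
    with pytest.raises(cs.ValidationError):
        cs.calibration([], [], 10)
    with pytest.raises(cs.ValidationError):
        cs.calibration([0.5], [1.0], 1)
    with pytest.raises(cs.ValidationError):
        cs.calibration([1.5], [1.0], 2)


def test_mean_trajectories_deterministic_drift():
    """Change probability 1, increment 1, no deaths: mean CCI climbs by
    exactly one per year in both generator and simulator."""
    truth = cs.constant_models(0.0, p_cci_change=1.0)
    spec = cs.default_spec(300, seed=16, truth=truth,
                           annual_censor_prob=0.0, max_followup=6)
    cohort = cs.generate_cohort(spec)
    panel = cs.simulate_entry_states(
        cohort.loc[cohort.year_index == 0, "age"].to_numpy(),
        cohort.loc[cohort.year_index == 0, "cci"].to_numpy(),
        cohort.loc[cohort.year_index == 0, "dci"].to_numpy(),
        truth, 6, seed=17, return_panel=True)
    out = cs.mean_trajectories(cohort, {"all": panel}, {"all": None})
    assert np.allclose(out["diff_cci"], 0.0)
    assert np.allclose(out["diff_dci"], 0.0)
    drift = out["mean_cci"].to_numpy() - out["mean_cci"].iloc[0]
    assert np.allclose(drift, out["t"].to_numpy())


def test_crossval_requires_multiple_regions(small_cohort):
    one = small_cohort.copy()
    one["region"] = 1
    with pytest.raises(cs.ValidationError):
        cs.region_cross_validation(one, seed=1)


def test_crossval_label_permutation_invariance(truth):
    spec = cs.default_spec(2500, seed=18, truth=truth, n_regions=3)
    cohort = cs.generate_cohort(spec)
    perm = {1: 3, 2: 1, 3: 2}
    permuted = cohort.copy()
    permuted["region"] = permuted["region"].map(perm)
    a = cs.region_cross_validation(cohort, seed=5, replicates=2,
                                   horizon=8)
    b = cs.region_cross_validation(permuted, seed=5, replicates=2,
                                   horizon=8)
    for r in (1, 2, 3):
        assert np.array_equal(a.reports[r].observed,
                              b.reports[perm[r]].observed)
        assert np.array_equal(a.reports[r].simulated,
                              b.reports[perm[r]].simulated)


def test_crossval_skips_absent_region(small_cohort):
    result = cs.region_cross_validation(
        small_cohort.iloc[:5000], seed=3, replicates=1, horizon=5,
        regions=[1, 2, 99])
    assert 99 in result.skipped
    assert 1 in result.reports and 2 in result.reports
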