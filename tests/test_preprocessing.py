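"""Trial derivation, exclusion rules and condition grouping."""

import numpy as np
import pandas as pd
import pytest

from sdfaces import (
    condition_keys,
    derive_trials,
    filter_trials,
    group_by_condition,
    read_trials,
    signed_distance,
    write_trials,
)

from conftest import make_trials


def test_derive_simple_arithmetic(wheel):
    t = make_trials([{"face1": 10, "face2": 0, "response": 3}])
    d = derive_trials(t, wheel, 1)
    assert d.loc[0, "target"] == 0 and d.loc[0, "inducer"] == 10
    assert d.loc[0, "error"] == 3
    assert d.loc[0, "delta"] == 10


def test_derive_with_wraparound(wheel):
    t = make_trials([{"face1": 0, "face2": 130, "response": 135}])
    d = derive_trials(t, wheel, 1)
    assert d.loc[0, "error"] == 5
    assert d.loc[0, "delta"] == 11


def test_derive_postcue_role_swap(wheel):
    t = make_trials(
        [{"face1": 20, "face2": 60, "postcue": 1, "response": 25},
         {"face1": 20, "face2": 60, "postcue": 2, "response": 25}],
        experiment=2,
    )
    d = derive_trials(t, wheel, 2)
    r1 = d[d["postcue"] == 1].iloc[0]
    assert r1["target"] == 20 and r1["inducer"] == 60
    assert r1["error"] == 5 and r1["delta"] == 40
    r2 = d[d["postcue"] == 2].iloc[0]
    assert r2["target"] == 60 and r2["inducer"] == 20
    assert r2["error"] == -35 and r2["delta"] == -40


def test_experiment_postcue_contracts(wheel):
    with pytest.raises(ValueError):
        derive_trials(make_trials([{"postcue": 1}]), wheel, 1)
    t2 = make_trials([{}], experiment=2)
    t2.loc[0, "postcue"] = np.nan
    with pytest.raises(ValueError):
        derive_trials(t2, wheel, 2)


def test_filter_boundary_cases(wheel):
    rows = [{"response": 0, "rt_s": 5.0} for _ in range(8)]
    rows.append({"response": 0, "rt_s": 16.0})          # removed: slow
    rows.append({"response": 61, "rt_s": 5.0})          # removed: error +61
    d = derive_trials(make_trials(rows), wheel, 1)
    kept, frac = filter_trials(d)
    assert len(kept) == 8
    assert frac == pytest.approx(0.20)


def test_filter_keeps_exact_thresholds(wheel):
    rows = [
        {"response": 60, "rt_s": 15.0},   # both at the limit: kept
        {"response": 81, "rt_s": 5.0},    # error -60: kept
        {"response": 0, "rt_s": 5.0},
    ]
    d = derive_trials(make_trials(rows), wheel, 1)
    assert d.loc[0, "error"] == 60 and d.loc[1, "error"] == -60
    kept, frac = filter_trials(d)
    assert len(kept) == 3 and frac == 0.0


def test_double_failure_counts_once(wheel):
    rows = [{"response": 0, "rt_s": 5.0}, {"response": 70, "rt_s": 20.0}]
    d = derive_trials(make_trials(rows), wheel, 1)
    assert d.loc[1, "exclude_reason"] == "rt+error"
    _, frac = filter_trials(d)
    assert frac == pytest.approx(0.5)


def test_group_by_condition_balanced_session(derived_exp1):
    kept = derived_exp1  # include excluded: schedule balance is on all trials
    groups = group_by_condition(kept, 1)
    assert len(groups) == 20
    assert all(len(g) == 9 * 2 for g in groups.values())  # 2 sessions


def test_group_by_condition_exp2(small_exp2, wheel):
    d = derive_trials(small_exp2, wheel, 2)
    groups = group_by_condition(d, 2)
    assert len(groups) == 6
    assert all(len(g) == 50 * 2 for g in groups.values())


def test_single_trial_grouping(wheel):
    d = derive_trials(make_trials([{"isi_s": 3, "delay_s": 6}]), wheel, 1)
    groups = group_by_condition(d, 1)
    sizes = {k: len(v) for k, v in groups.items()}
    assert sizes[(3, 6)] == 1
    assert sum(sizes.values()) == 1
    assert len(groups) == 20


def test_group_sizes_sum_to_kept_count(derived_exp1):
    kept, _ = filter_trials(derived_exp1)
    groups = group_by_condition(kept, 1)
    assert sum(len(g) for g in groups.values()) == len(kept)


def test_derivation_order_invariance(small_exp1, wheel):
    shuffled = small_exp1.sample(frac=1.0, random_state=1)
    d1 = derive_trials(small_exp1, wheel, 1).reset_index(drop=True)
    d2 = derive_trials(shuffled, wheel, 1).reset_index(drop=True)
    pd.testing.assert_frame_equal(d1, d2)


def test_error_round_trip(derived_exp1, wheel):
    kept, _ = filter_trials(derived_exp1)
    re_err = signed_distance(
        kept["target"].to_numpy(), kept["response"].to_numpy(), wheel
    )
    np.testing.assert_array_equal(re_err, kept["error"].to_numpy())


def test_csv_round_trip(tmp_path, derived_exp1):
    p = tmp_path / "trials.csv"
    write_trials(derived_exp1, p)
    back = read_trials(p)
    assert len(back) == len(derived_exp1)
    np.testing.assert_array_equal(
        back["error"].to_numpy(), derived_exp1["error"].to_numpy()
    )


def test_unknown_column_warns(tmp_path, small_exp1):
    p = tmp_path / "trials.csv"
    extra = small_exp1.assign(gaze_x=0.0)
    extra.to_csv(p, index=False)
    with pytest.warns(UserWarning, match="gaze_x"):
        back = read_trials(p)
    assert "gaze_x" not in back.columns


def test_condition_keys_counts():
    assert len(condition_keys(1)) == 20
    assert len(condition_keys(2)) == 6
    with pytest.raises(ValueError):
        condition_keys(3)
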