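"""Treatment coding, lags, diary scores, analysis-table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dyadmrt as d
from dyadmrt.design import DELIVERY_COLUMNS, phase_schedule
from dyadmrt.features import (
    assemble,
    barrier_facilitator_scores,
    code_targets,
    lag_indicators,
)


def _delivery(couple=1, day=10, jitai_id="x", jitai_type="cross-over",
              timing="before_activity", executor="1", target="2", target_days=(10,)):
    return {
        "couple_id": couple, "day": day, "jitai_id": jitai_id, "jitai_type": jitai_type,
        "timing": timing, "executor_member": executor, "target_member": target,
        "target_days": tuple(target_days),
    }


def _log(rows):
    return pd.DataFrame(rows, columns=DELIVERY_COLUMNS)


class TestCodeTargets:
    def test_crossover_sets_actor_for_target_and_partner_for_other(self):
        log = _log([_delivery(day=12, target="1", target_days=(12,))])
        m1 = code_targets(log, 1, 20)
        m2 = code_targets(log, 2, 20)
        assert m1.loc[12, "jitai_actor"] == 1 and m1.loc[12, "jitai_partner"] == 0
        assert m2.loc[12, "jitai_actor"] == 0 and m2.loc[12, "jitai_partner"] == 1
        assert m1.loc[12, "crossover_actor"] == 1
        assert m2.loc[12, "crossover_partner"] == 1

    def test_joint_targets_both_members_both_roles(self):
        log = _log([
            _delivery(day=18, jitai_type="joint", executor="both", target="1",
                      timing="evening", target_days=(20,)),
            _delivery(day=18, jitai_type="joint", executor="both", target="2",
                      timing="evening", target_days=(20,)),
        ])
        for member in (1, 2):
            coded = code_targets(log, member, 25)
            assert coded.loc[20, "jitai_actor"] == 1
            assert coded.loc[20, "jitai_partner"] == 1
            assert coded.loc[20, "joint"] == 1
            assert coded.loc[20, "timing_evening_actor"] == 1

    def test_empty_log_all_zero(self):
        coded = code_targets(_log([]), 1, 15)
        assert (coded.to_numpy() == 0).all()

    def test_unknown_member_errors(self):
        log = _log([_delivery(target="3")])
        with pytest.raises(ValueError, match="unknown member"):
            code_targets(log, 1, 20)

    def test_target_day_outside_study_errors(self):
        log = _log([_delivery(target_days=(99,))])
        with pytest.raises(ValueError, match="outside study days"):
            code_targets(log, 1, 20)

    def test_indicators_stay_binary_with_stacked_deliveries(self):
        log = _log([
            _delivery(day=10, jitai_id="a", target="1", target_days=(12,)),
            _delivery(day=11, jitai_id="b", target="1", target_days=(12,)),
        ])
        coded = code_targets(log, 1, 20)
        assert coded.loc[12, "jitai_actor"] == 1


class TestLagIndicators:
    def test_shift_by_one(self):
        got = lag_indicators(pd.Series([0, 1, 0, 0], index=range(1, 5)))
        assert got["lag1"].tolist() == [0, 0, 1, 0]

    def test_shift_by_three(self):
        got = lag_indicators(pd.Series([1, 0, 0, 0, 0], index=range(1, 6)))
        assert got["lag3"].tolist() == [0, 0, 0, 1, 0]

    def test_invalid_max_lag(self):
        with pytest.raises(ValueError):
            lag_indicators(pd.Series([0, 1]), max_lag=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=4, max_size=55))
    def test_matches_brute_force_shift(self, series):
        got = lag_indicators(pd.Series(series), max_lag=3)
        for k in (1, 2, 3):
            want = [series[i - k] if i - k >= 0 else 0 for i in range(len(series))]
            assert got[f"lag{k}"].tolist() == want


class TestBarrierFacilitatorScores:
    @pytest.mark.parametrize(
        "items, expected",
        [
            ((0,) * 8, (0, 0)),
            ((-5, -5, 0, 0, 0, 0, 0, 0), (10, 0)),
            ((3, -2, 1, 0, 0, 0, 0, 0), (2, 4)),
            ((5,) * 8, (0, 40)),
            ((-5,) * 8, (40, 0)),
        ],
    )
    def test_split_rule(self, items, expected):
        assert barrier_facilitator_scores(items) == expected

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match=r"\[-5, 5\]"):
            barrier_facilitator_scores((6, 0, 0, 0, 0, 0, 0, 0))

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError, match="8"):
            barrier_facilitator_scores((1, 2, 3))


class TestAssemble:
    def _sources(self, design):
        schedules = {1: phase_schedule("A", design)}
        n = design.n_days
        key = {"couple": 1}
        daily = pd.concat([
            pd.DataFrame({**key, "member": m, "day": range(1, n + 1),
                          "mvpa_min": 60, "wear_min": 800.0, "compliant": True})
            for m in (1, 2)
        ], ignore_index=True)
        daily.loc[(daily["member"] == 1) & (daily["day"] == 3), "compliant"] = False
        diary = pd.concat([
            pd.DataFrame({**key, "member": m, "day": range(1, n + 1),
                          "sr_alone": 20.0, "sr_together": 15.0,
                          **{f"item{i}": 0 for i in range(1, 9)}})
            for m in (1, 2)
        ], ignore_index=True)
        diary.loc[0, ["item1", "item2"]] = [-5, 3]
        log = _log([_delivery(day=12, target="1", target_days=(12,))])
        return daily, diary, log, schedules

    def test_assemble_fields(self, design):
        daily, diary, log, schedules = self._sources(design)
        table = assemble(daily, diary, log, schedules, design, groups={1: "A"})
        assert len(table) == 2 * design.n_days
        assert (table["y_self"] == 35.0).all()
        first = table[(table["member"] == 1) & (table["day"] == 1)].iloc[0]
        assert first["barriers"] == 5 and first["facilitators"] == 3
        # day 1 is a Saturday, day 4 a Tuesday
        assert first["weekend"] == 1
        assert table[table["day"] == 4]["weekend"].eq(0).all()
        # centered time vanishes exactly at the middle day of the complete grid
        assert table[table["day"] == 28]["time_c"].abs().max() < 1e-12
        # non-compliant day becomes a missing device outcome
        assert np.isnan(table[(table["member"] == 1) & (table["day"] == 3)]["y_device"]).all()
        # skilled support switches on at day 8 for group A
        assert (table[table["day"] < 8]["skilled_support"] == 0).all()
        assert (table[table["day"] >= 8]["skilled_support"] == 1).all()
        m1 = table[table["member"] == 1].set_index("day")
        m2 = table[table["member"] == 2].set_index("day")
        assert m1.loc[12, "jitai_actor"] == 1 and m2.loc[12, "jitai_partner"] == 1

    def test_duplicate_rows_error(self, design):
        daily, diary, log, schedules = self._sources(design)
        dup = pd.concat([daily, daily.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            assemble(dup, diary, log, schedules, design)

    def test_wear_centering_over_observed_rows(self, design):
        daily, diary, log, schedules = self._sources(design)
        table = assemble(daily, diary, log, schedules, design)
        observed = table[table["y_device"].notna()]
        assert abs(observed["wear_c"].mean()) < 1e-10


def test_assemble_reproduces_simulated_table():
    """Feature assembly on the raw simulated sources matches the direct table."""
    cfg = d.SimConfig(n_couples=6, seed=31)
    table, log, _, raw = d.simulate_trial(cfg, return_raw=True)
    groups = table[["couple", "group"]].drop_duplicates().set_index("couple")["group"].to_dict()
    schedules = {c: phase_schedule(g, cfg.design) for c, g in groups.items()}
    rebuilt = assemble(
        raw["daily_device"], raw["diary"], log, schedules, cfg.design,
        groups=groups, planned=raw["planned"],
    )
    merged = table.merge(rebuilt, on=["couple", "member", "day"], suffixes=("", "_rb"))
    assert len(merged) == len(table)
    for col in ("phase", "planned", "weekend", "skilled_support",
                "jitai_actor", "jitai_partner", "joint", "group_B", "group_C"):
        assert (merged[col] == merged[f"{col}_rb"]).all(), col
    for col in ("y_device", "y_self", "time_c"):
        pd.testing.assert_series_equal(
            merged[col], merged[f"{col}_rb"], check_names=False, atol=1e-9
        )
    observed = merged["y_self"].notna()
    assert (merged.loc[observed, "barriers"] == merged.loc[observed, "barriers_rb"]).all()
    assert (merged.loc[observed, "facilitators"] == merged.loc[observed, "facilitators_rb"]).all()


def test_type_and_timing_splits_partition_events(proximal_trial):
    table, _, _ = proximal_trial
    type_sum = table[["crossover_actor", "joint"]].max(axis=1)
    timing_max = table[
        ["timing_planning_actor", "timing_activity_actor", "timing_evening_actor"]
    ].max(axis=1)
    # both splits mark exactly the actor-targeted days
    assert (type_sum == table["jitai_actor"]).all()
    assert (timing_max == table["jitai_actor"]).all()
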