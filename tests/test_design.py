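"""Trial design: blocked allocation, phase schedules, JITAI randomization."""

import collections
import io

import numpy as np
import pandas as pd
import pytest

from dyadmrt.design import (
    JitaiSpec,
    TrialDesign,
    allocate_groups,
    delivery_log_from_csv,
    delivery_log_to_csv,
    design_from_yaml,
    phase_schedule,
    planning_days,
    randomize_jitais,
    timing_to_target_days,
)


class TestAllocateGroups:
    def test_equal_blocks(self):
        alloc = allocate_groups(range(6), seed=0)
        counts = collections.Counter(alloc.values())
        assert counts == {"A": 2, "B": 2, "C": 2}

    def test_study_size_partial_block(self):
        alloc = allocate_groups(range(38), seed=3)
        counts = sorted(collections.Counter(alloc.values()).values())
        assert counts == [12, 13, 13]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            allocate_groups([], seed=0)

    def test_deterministic(self):
        assert allocate_groups(range(9), seed=5) == allocate_groups(range(9), seed=5)

    def test_block_permutations_uniform(self):
        # every ordering of one block of 3 should appear with frequency 1/6
        orderings = collections.Counter()
        for seed in range(10_000):
            alloc = allocate_groups([0, 1, 2], seed=seed)
            orderings[(alloc[0], alloc[1], alloc[2])] += 1
        assert len(orderings) == 6
        freqs = np.array(list(orderings.values())) / 10_000
        # 1/6 +- 4 binomial SDs
        tol = 4 * np.sqrt((1 / 6) * (5 / 6) / 10_000)
        assert np.all(np.abs(freqs - 1 / 6) < tol)


class TestPhaseSchedule:
    def test_group_a(self, design):
        s = phase_schedule("A", design)
        assert all(s.phase(d) == "control" for d in range(1, 8))
        assert all(s.phase(d) == "intervention" for d in range(8, 56))
        assert len(s.intervention_days()) == 48

    def test_group_b_boundaries(self, design):
        s = phase_schedule("B", design)
        assert s.phase(28) == "intervention"
        assert s.phase(29) == "control"
        assert s.phase(55) == "control"

    def test_group_c(self, design):
        s = phase_schedule("C", design)
        assert all(s.phase(d) == "control" for d in range(1, 36))
        assert all(s.phase(d) == "intervention" for d in range(36, 56))

    @pytest.mark.parametrize("group", ["A", "B", "C"])
    def test_shared_baseline_week_and_length(self, group, design):
        s = phase_schedule(group, design)
        assert all(s.phase(d) == "control" for d in range(1, 8))
        assert s.n_days == design.n_days == 55

    def test_skilled_support_is_first_intervention_saturday(self, design):
        # day 1 is a Saturday, so day 8 (A, B) and day 36 (C) are Saturdays
        assert phase_schedule("A", design).skilled_support_day == 8
        assert phase_schedule("B", design).skilled_support_day == 8
        assert phase_schedule("C", design).skilled_support_day == 36

    def test_unknown_group(self, design):
        with pytest.raises(ValueError, match="unknown group"):
            phase_schedule("D", design)

    def test_longer_trial_extends_final_phase(self):
        design = TrialDesign(n_days=60)
        s = phase_schedule("A", design)
        assert s.n_days == 60
        assert s.phase(60) == "intervention"

    def test_planning_days_are_intervention_sundays(self, design):
        s = phase_schedule("A", design)
        days = planning_days(s, design)
        assert days[0] == 9  # first Sunday after the control week
        assert all(design.weekday(d) == "sunday" for d in days)
        assert all(s.phase(d) == "intervention" for d in days)


class TestTimingToTargetDays:
    def test_before_activity_on_planned_day(self):
        assert timing_to_target_days("before_activity", 15, {15, 20}) == {15}

    def test_before_activity_needs_plan(self):
        assert timing_to_target_days("before_activity", 15, {20}) == set()

    def test_evening_targets_next_planned(self):
        assert timing_to_target_days("evening", 12, {10, 14, 20}) == {14}

    def test_evening_without_later_plan_is_empty(self):
        assert timing_to_target_days("evening", 30, {10, 14}) == set()

    def test_before_planning_targets_next_week(self):
        got = timing_to_target_days(
            "before_planning", 8, {10, 12, 20}, planning_session_days=[9, 16]
        )
        assert got == {10, 12}

    def test_unknown_timing(self):
        with pytest.raises(ValueError):
            timing_to_target_days("midnight", 3, set())


class TestRandomizeJitais:
    def _planned(self, schedule, every=2):
        days = schedule.intervention_days()
        return {1: set(days[::every]), 2: set(days[1::every])}

    def test_prob_zero_all_control(self, design):
        s = phase_schedule("A", design)
        log = randomize_jitais(
            s, TrialDesign(jitai_prob=0.0), self._planned(s), seed=0
        )
        assert (log["jitai_id"] == "").all()
        assert set(log["day"]) == set(s.intervention_days())

    def test_deliveries_only_on_intervention_days(self, design):
        s = phase_schedule("B", design)
        for seed in range(50):
            log = randomize_jitais(s, design, self._planned(s), seed=seed)
            delivered = log[log["jitai_id"] != ""]
            assert set(delivered["day"]) <= set(s.intervention_days())

    def test_target_days_inside_study(self, design):
        s = phase_schedule("A", design)
        log = randomize_jitais(s, design, self._planned(s), seed=7)
        for tdays in log["target_days"]:
            assert all(1 <= t <= design.n_days for t in tdays)

    def test_delivery_frequency_matches_probability(self, design):
        # with an always-feasible catalogue every intervention day is eligible
        catalogue = (JitaiSpec("act", "cross-over", "before_activity"),)
        d2 = TrialDesign(jitai_prob=0.5, catalogue=catalogue)
        s = phase_schedule("A", d2)
        planned = {1: set(s.intervention_days()), 2: set(s.intervention_days())}
        delivered = total = 0
        seed = 0
        while total < 10_000:
            log = randomize_jitais(s, d2, planned, seed=seed)
            per_day = log.groupby("day")["jitai_id"].first()
            delivered += int((per_day != "").sum())
            total += len(per_day)
            seed += 1
        phat = delivered / total
        assert abs(phat - 0.5) < 2.6 * np.sqrt(0.25 / total)  # ~99% band

    def test_empty_catalogue_with_positive_prob(self, design):
        s = phase_schedule("A", design)
        with pytest.raises(ValueError, match="catalogue"):
            TrialDesign(jitai_prob=0.5, catalogue=())

    def test_planned_days_outside_intervention_error(self, design):
        s = phase_schedule("A", design)
        with pytest.raises(ValueError, match="outside the intervention phase"):
            randomize_jitais(s, design, {1: {2}, 2: set()}, seed=0)

    def test_reproducible(self, design):
        s = phase_schedule("C", design)
        a = randomize_jitais(s, design, self._planned(s), seed=11)
        b = randomize_jitais(s, design, self._planned(s), seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestJitaiSpecInvariants:
    def test_joint_requires_both(self):
        with pytest.raises(ValueError):
            JitaiSpec("x", "joint", "evening", executor="one_member", target="both")

    def test_crossover_requires_one_member(self):
        with pytest.raises(ValueError):
            JitaiSpec("x", "cross-over", "evening", executor="both", target="partner")


def test_delivery_log_csv_roundtrip(design):
    s = phase_schedule("A", design)
    planned = {1: set(s.intervention_days()[::3]), 2: set(s.intervention_days()[1::3])}
    log = randomize_jitais(s, design, planned, seed=4, couple_id=9)
    buf = io.StringIO()
    delivery_log_to_csv(log, buf)
    back = delivery_log_from_csv(io.StringIO(buf.getvalue()))
    pd.testing.assert_frame_equal(log, back)


def test_design_from_yaml_roundtrip():
    text = """
n_days: 28
jitai_prob: 0.3
day1_weekday: saturday
catalogue:
  - {id: a, jitai_type: cross-over, timing: evening, executor: one_member, target: partner}
  - {id: b, jitai_type: joint, timing: before_planning, executor: both, target: both}
"""
    design = design_from_yaml(text)
    assert design.n_days == 28
    assert design.jitai_prob == 0.3
    assert [c.id for c in design.catalogue] == ["a", "b"]
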