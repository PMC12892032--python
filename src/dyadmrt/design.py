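"""Trial design: group schedules, planning calendar, and daily JITAI randomization.

The trial runs over ``n_days`` (default 55) with couples block-randomized to
three groups that differ only in when the intervention phase occurs.  Every
group shares a first control week.  During the intervention phase a daily
randomization either delivers one dyadic just-in-time adaptive intervention
(JITAI) from a catalogue, or leaves the day as an embedded control day.

Day indexing is 1-based.  Day 1 falls on ``day1_weekday`` (default Saturday),
so the skilled-support psychoeducation session lands on the first Saturday of
a couple's first intervention phase, and weekly planning sessions land on the
Sundays inside the intervention phase.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "JitaiSpec",
    "TrialDesign",
    "PhaseSchedule",
    "default_catalogue",
    "design_from_yaml",
    "allocate_groups",
    "phase_schedule",
    "timing_to_target_days",
    "randomize_jitais",
    "delivery_log_to_csv",
    "delivery_log_from_csv",
]

WEEKDAYS = ["monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday"]

JITAI_TYPES = ("cross-over", "joint")
TIMINGS = ("before_planning", "before_activity", "evening")
EXECUTORS = ("one_member", "both")
TARGETS = ("actor", "partner", "both")

DELIVERY_COLUMNS = [
    "couple_id",
    "day",
    "jitai_id",
    "jitai_type",
    "timing",
    "executor_member",
    "target_member",
    "target_days",
]


@dataclass(frozen=True)
class JitaiSpec:
    """One catalogue entry for the daily JITAI randomization.

    ``executor`` is who receives the prompt; ``target`` says whose physical
    activity the content aims at, relative to the executor.  A joint JITAI is
    sent to and targets both members; a cross-over JITAI is sent to one member
    and either targets that member's own activity (``actor``, e.g. "ask your
    partner for support") or the other member's (``partner``, e.g. "provide
    emotional support to your partner").
    """

    id: str
    jitai_type: str
    timing: str
    executor: str = "one_member"
    target: str = "partner"

    def __post_init__(self) -> None:
        if self.jitai_type not in JITAI_TYPES:
            raise ValueError(f"unknown jitai_type {self.jitai_type!r}")
        if self.timing not in TIMINGS:
            raise ValueError(f"unknown timing {self.timing!r}")
        if self.executor not in EXECUTORS:
            raise ValueError(f"unknown executor {self.executor!r}")
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.jitai_type == "joint" and (self.executor != "both" or self.target != "both"):
            raise ValueError("joint JITAIs require executor='both' and target='both'")
        if self.jitai_type == "cross-over" and self.executor != "one_member":
            raise ValueError("cross-over JITAIs require executor='one_member'")


def default_catalogue() -> list[JitaiSpec]:
    """Cross-over (both target directions) and joint entries at every timing."""
    entries = []
    for timing in TIMINGS:
        short = {"before_planning": "plan", "before_activity": "act", "evening": "eve"}[timing]
        entries.append(
            JitaiSpec(f"xo_partner_{short}", "cross-over", timing, "one_member", "partner")
        )
        entries.append(JitaiSpec(f"xo_actor_{short}", "cross-over", timing, "one_member", "actor"))
        entries.append(JitaiSpec(f"joint_{short}", "joint", timing, "both", "both"))
    return entries


@dataclass(frozen=True)
class TrialDesign:
    n_days: int = 55
    groups: tuple[str, ...] = ("A", "B", "C")
    day1_weekday: str = "saturday"
    jitai_prob: float = 0.5
    catalogue: tuple[JitaiSpec, ...] = field(default_factory=lambda: tuple(default_catalogue()))
    planning_weekday: str = "sunday"

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitai_prob <= 1.0:
            raise ValueError("jitai_prob must be in [0, 1]")
        if self.n_days < 14:
            raise ValueError("n_days must be at least 14 (one control week plus intervention)")
        if self.jitai_prob > 0 and len(self.catalogue) == 0:
            raise ValueError("catalogue must be non-empty when jitai_prob > 0")
        if self.day1_weekday.lower() not in WEEKDAYS:
            raise ValueError(f"unknown weekday {self.day1_weekday!r}")
        if self.planning_weekday.lower() not in WEEKDAYS:
            raise ValueError(f"unknown weekday {self.planning_weekday!r}")
        object.__setattr__(self, "catalogue", tuple(self.catalogue))

    def weekday(self, day: int) -> str:
        """Weekday name of a 1-based study day."""
        start = WEEKDAYS.index(self.day1_weekday.lower())
        return WEEKDAYS[(start + day - 1) % 7]

    def is_weekend(self, day: int) -> bool:
        return self.weekday(day) in ("saturday", "sunday")


def design_from_yaml(source) -> TrialDesign:
    """Load a :class:`TrialDesign` from a YAML mapping.

    Recognized keys: ``n_days``, ``groups``, ``day1_weekday``, ``jitai_prob``,
    ``planning_weekday`` and ``catalogue`` (a list of mappings with keys
    ``id``, ``jitai_type``, ``timing``, ``executor``, ``target``).
    """
    if isinstance(source, (str, bytes)):
        data = yaml.safe_load(source)
    else:
        data = yaml.safe_load(source.read() if hasattr(source, "read") else str(source))
    if not isinstance(data, dict):
        raise ValueError("design config must be a mapping")
    kwargs = {}
    for key in ("n_days", "day1_weekday", "jitai_prob", "planning_weekday"):
        if key in data:
            kwargs[key] = data[key]
    if "groups" in data:
        kwargs["groups"] = tuple(data["groups"])
    if "catalogue" in data:
        kwargs["catalogue"] = tuple(JitaiSpec(**entry) for entry in data["catalogue"])
    return TrialDesign(**kwargs)


# ---------------------------------------------------------------------------
# Phase schedules
# ---------------------------------------------------------------------------

# Week-block plans per group: shared control week, then group-specific blocks.
_GROUP_WEEK_PLAN = {
    "A": [("control", 1), ("intervention", 7)],
    "B": [("control", 1), ("intervention", 3), ("control", 4)],
    "C": [("control", 1), ("control", 4), ("intervention", 3)],
}


@dataclass(frozen=True)
class PhaseSchedule:
    group: str
    phase_by_day: tuple[str, ...]  # "control" | "intervention", index 0 == day 1
    skilled_support_day: int

    @property
    def n_days(self) -> int:
        return len(self.phase_by_day)

    def phase(self, day: int) -> str:
        return self.phase_by_day[day - 1]

    def intervention_days(self) -> list[int]:
        return [d for d in range(1, self.n_days + 1) if self.phase(d) == "intervention"]


def phase_schedule(group: str, design: TrialDesign | None = None) -> PhaseSchedule:
    """Expand a group's week-block plan into a per-day phase sequence.

    The nominal week plan totals 56 days; the final block is truncated (or
    extended) so the schedule is exactly ``design.n_days`` long.  The
    skilled-support session day is the first day of the first intervention
    phase that falls on a Saturday.
    """
    design = design or TrialDesign()
    if group not in _GROUP_WEEK_PLAN:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(_GROUP_WEEK_PLAN)}")
    days: list[str] = []
    for phase, weeks in _GROUP_WEEK_PLAN[group]:
        days.extend([phase] * (7 * weeks))
    if len(days) >= design.n_days:
        days = days[: design.n_days]
    else:  # extend the final phase to cover a longer trial
        days.extend([days[-1]] * (design.n_days - len(days)))
    first_block = [d for d in range(1, design.n_days + 1) if days[d - 1] == "intervention"]
    if not first_block:
        raise ValueError(f"group {group!r} schedule has no intervention days at n_days={design.n_days}")
    skilled = next(
        (d for d in first_block if design.weekday(d) == "saturday"), first_block[0]
    )
    return PhaseSchedule(group=group, phase_by_day=tuple(days), skilled_support_day=skilled)


def planning_days(schedule: PhaseSchedule, design: TrialDesign | None = None) -> list[int]:
    """Weekly planning-session days: the planning weekday within the intervention phase."""
    design = design or TrialDesign()
    return [
        d
        for d in schedule.intervention_days()
        if design.weekday(d) == design.planning_weekday.lower()
    ]


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------


def allocate_groups(couple_ids, seed: int, groups: tuple[str, ...] = ("A", "B", "C")) -> dict:
    """Blocked randomization of couples to groups.

    Couples are taken in blocks the size of the group list and a uniformly
    random permutation of the groups is assigned within each block; a final
    partial block receives the first entries of one more random permutation.
    Resulting group sizes differ by at most one.
    """
    couple_ids = list(couple_ids)
    if len(couple_ids) == 0:
        raise ValueError("couple_ids must be non-empty")
    rng = np.random.default_rng(seed)
    k = len(groups)
    allocation: dict = {}
    for start in range(0, len(couple_ids), k):
        block = couple_ids[start : start + k]
        perm = rng.permutation(k)
        for cid, g in zip(block, perm):
            allocation[cid] = groups[g]
    return allocation


def timing_to_target_days(
    timing: str,
    delivery_day: int,
    planned_days,
    planning_session_days=(),
) -> set[int]:
    """Map a delivery day to the days on which the JITAI targets activity.

    * ``before_activity`` — targets the delivery day itself, provided that day
      is a planned-activity day (otherwise the prompt has no occasion: empty).
    * ``evening`` — targets the next planned day strictly after delivery
      (reflection ahead of the next occasion); empty if none remains.
    * ``before_planning`` — targets every planned day in the week following
      the next planning session (the prompt shapes that session's plans).
    """
    planned = set(planned_days)
    if timing == "before_activity":
        return {delivery_day} if delivery_day in planned else set()
    if timing == "evening":
        later = [d for d in planned if d > delivery_day]
        return {min(later)} if later else set()
    if timing == "before_planning":
        sessions = [q for q in planning_session_days if q >= delivery_day]
        if not sessions:
            return set()
        q = min(sessions)
        return {d for d in planned if q < d <= q + 7}
    raise ValueError(f"unknown timing {timing!r}")


def _empty_delivery_row(couple_id, day):
    return {
        "couple_id": couple_id,
        "day": day,
        "jitai_id": "",
        "jitai_type": "",
        "timing": "",
        "executor_member": "",
        "target_member": "",
        "target_days": tuple(),
    }


def randomize_jitais(
    schedule: PhaseSchedule,
    design: TrialDesign,
    planned_days: dict,
    seed: int,
    couple_id=0,
) -> pd.DataFrame:
    """Run the daily JITAI randomization over one couple's intervention phase.

    ``planned_days`` maps member (1, 2) to that member's planned-activity
    days; plans must lie inside the intervention phase.  Each intervention
    day, with probability ``design.jitai_prob`` one catalogue entry is drawn
    uniformly among entries whose timing yields a non-empty target-day set;
    otherwise (or if no entry is feasible) the day is logged as an embedded
    control day.  Returns a delivery log with one row per (delivery,
    targeted member) plus one empty-``jitai_id`` row per control day.
    """
    if design.jitai_prob > 0 and len(design.catalogue) == 0:
        raise ValueError("catalogue must be non-empty when jitai_prob > 0")
    interv = set(schedule.intervention_days())
    for m, days in planned_days.items():
        stray = set(days) - interv
        if stray:
            raise ValueError(f"member {m} has planned days outside the intervention phase: {sorted(stray)}")
    sessions = planning_days(schedule, design)
    rng = np.random.default_rng(seed)
    rows = []
    for day in sorted(interv):
        if rng.random() >= design.jitai_prob:
            rows.append(_empty_delivery_row(couple_id, day))
            continue
        # executor draw is made regardless of eligibility to keep the stream stable
        exec_draw = int(rng.integers(1, 3))
        candidates = []
        for entry in design.catalogue:
            if entry.jitai_type == "joint":
                targets = {1: None, 2: None}
            elif entry.target == "actor":
                targets = {exec_draw: None}
            else:  # cross-over targeting the partner
                targets = {3 - exec_draw: None}
            per_member = {
                m: timing_to_target_days(entry.timing, day, planned_days.get(m, ()), sessions)
                for m in targets
            }
            if entry.jitai_type == "joint":
                # joint JITAIs target both members on the same days
                union = set().union(*per_member.values())
                per_member = {m: union for m in per_member}
            if any(per_member.values()):
                candidates.append((entry, per_member))
        if not candidates:
            rows.append(_empty_delivery_row(couple_id, day))
            continue
        entry, per_member = candidates[int(rng.integers(len(candidates)))]
        executor = "both" if entry.executor == "both" else str(exec_draw)
        for m, tdays in sorted(per_member.items()):
            rows.append(
                {
                    "couple_id": couple_id,
                    "day": day,
                    "jitai_id": entry.id,
                    "jitai_type": entry.jitai_type,
                    "timing": entry.timing,
                    "executor_member": executor,
                    "target_member": str(m),
                    "target_days": tuple(sorted(tdays)),
                }
            )
    return pd.DataFrame(rows, columns=DELIVERY_COLUMNS)


# ---------------------------------------------------------------------------
# Delivery-log serialization
# ---------------------------------------------------------------------------


def delivery_log_to_csv(log: pd.DataFrame, path_or_buf=None):
    """Write a delivery log as CSV; target_days are semicolon-joined integers."""
    out = log.copy()
    out["target_days"] = out["target_days"].map(lambda t: ";".join(str(d) for d in t))
    return out.to_csv(path_or_buf, index=False)


def delivery_log_from_csv(path_or_buf) -> pd.DataFrame:
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    log = pd.read_csv(
        path_or_buf,
        dtype={"jitai_id": str, "jitai_type": str, "timing": str,
               "executor_member": str, "target_member": str, "target_days": str},
        keep_default_na=False,
    )
    log["target_days"] = log["target_days"].map(
        lambda s: tuple(int(x) for x in str(s).split(";") if x != "")
    )
    return log[DELIVERY_COLUMNS]
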