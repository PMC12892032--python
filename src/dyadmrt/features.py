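"""Construction of the long-format person-day analysis table.

One row per (couple, member, day) carrying the outcomes (device and
self-reported MVPA minutes), the treatment indicators derived from the
delivery log (actor/partner, type split, timing split, lags 1-3), the phase
and planning indicators, and the covariates (centered time and wear time,
weekend, skilled support, barriers/facilitators, group dummies).

Coding rules
------------
* ``jitai_actor`` is 1 on days a delivery's target-day set for this member
  contains the day; ``jitai_partner`` is 1 on days a delivery targets the
  other member.  Joint JITAIs target both members, so they set all four
  indicators across the couple.  Indicators stay binary when several
  deliveries hit the same member-day (dummy coding, no dose accumulation).
* Lags shift the *target-day* indicator series by whole days.
* Barriers and facilitators split the 8 bipolar diary items (each in
  [-5, 5]) into two non-negative sums: negative poles accumulate into
  barriers, positive poles into facilitators.
* Time is centered per 7 days: ``time_c = (day - mean(day)) / 7``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import PhaseSchedule, TrialDesign

__all__ = [
    "code_targets",
    "lag_indicators",
    "barrier_facilitator_scores",
    "assemble",
    "TREATMENT_COLUMNS",
]

TREATMENT_COLUMNS = [
    "jitai_actor",
    "jitai_partner",
    "crossover_actor",
    "crossover_partner",
    "joint",
    "timing_planning_actor",
    "timing_planning_partner",
    "timing_activity_actor",
    "timing_activity_partner",
    "timing_evening_actor",
    "timing_evening_partner",
]

_TIMING_SHORT = {"before_planning": "planning", "before_activity": "activity", "evening": "evening"}


def code_targets(log: pd.DataFrame, member: int, n_days: int) -> pd.DataFrame:
    """Per-day treatment indicators for one member of one couple.

    ``log`` is a single couple's delivery log (one row per delivery x
    targeted member).  Returns a day-indexed frame (1..n_days) with the
    actor/partner indicators and their type and timing splits.
    """
    if member not in (1, 2):
        raise ValueError("member must be 1 or 2")
    arrays = {c: np.zeros(n_days, dtype=int) for c in TREATMENT_COLUMNS}
    deliveries = log[log["jitai_id"] != ""]
    for jtype, timing, tm, tdays in zip(
        deliveries["jitai_type"],
        deliveries["timing"],
        deliveries["target_member"],
        deliveries["target_days"],
    ):
        if str(tm) not in ("1", "2"):
            raise ValueError(f"delivery references unknown member {tm!r}")
        role = "actor" if int(tm) == member else "partner"
        for day in tdays:
            if not 1 <= day <= n_days:
                raise ValueError(f"target day {day} outside study days 1..{n_days}")
            idx = day - 1
            arrays[f"jitai_{role}"][idx] = 1
            if jtype == "joint":
                arrays["joint"][idx] = 1
            else:
                arrays[f"crossover_{role}"][idx] = 1
            arrays[f"timing_{_TIMING_SHORT[timing]}_{role}"][idx] = 1
    return pd.DataFrame(arrays, index=pd.RangeIndex(1, n_days + 1, name="day"))


def lag_indicators(series, max_lag: int = 3) -> pd.DataFrame:
    """Lagged copies of a day-indexed 0/1 indicator series.

    ``lag_k(day) = series(day - k)`` for ``day > k`` and 0 otherwise.  The
    input series must already be on the target-day scale (lags describe how
    many days ago the JITAI targeted activity, not when it was delivered).
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    values = np.asarray(series, dtype=int)
    out = {}
    for k in range(1, max_lag + 1):
        lagged = np.zeros_like(values)
        lagged[k:] = values[:-k]
        out[f"lag{k}"] = lagged
    idx = series.index if isinstance(series, pd.Series) else pd.RangeIndex(1, len(values) + 1)
    return pd.DataFrame(out, index=idx)


def barrier_facilitator_scores(items) -> tuple[int, int]:
    """Split 8 bipolar diary items into (barriers, facilitators) sums.

    Each item lies in [-5, 5]; the negative poles sum (sign-flipped) into the
    barrier score and the positive poles into the facilitator score, so both
    scores lie in [0, 40].
    """
    items = np.asarray(items)
    if items.shape != (8,):
        raise ValueError("expected exactly 8 bipolar items")
    if np.any(items < -5) or np.any(items > 5):
        raise ValueError("items must lie in [-5, 5]")
    barriers = int(np.sum(np.maximum(-items, 0)))
    facilitators = int(np.sum(np.maximum(items, 0)))
    return barriers, facilitators


def _coded_treatments(log: pd.DataFrame, n_days: int) -> pd.DataFrame:
    """Treatment indicators with lags for both members of one couple, long format."""
    frames = []
    for member in (1, 2):
        coded = code_targets(log, member, n_days)
        for base in ("jitai_actor", "jitai_partner"):
            lags = lag_indicators(coded[base], max_lag=3)
            lags.columns = [f"{base}_{c}" for c in lags.columns]
            coded = pd.concat([coded, lags], axis=1)
        coded = coded.reset_index()
        coded["member"] = member
        frames.append(coded)
    return pd.concat(frames, ignore_index=True)


def assemble(
    daily_device: pd.DataFrame,
    diary: pd.DataFrame,
    log: pd.DataFrame,
    schedules: dict,
    design: TrialDesign | None = None,
    groups: dict | None = None,
    planned: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join all sources into the analysis table, one row per person-day.

    Parameters
    ----------
    daily_device : frame with couple, member, day, mvpa_min, wear_min,
        compliant (or already y_device/wear_min with missing encoded as NaN).
    diary : frame with couple, member, day, sr_alone, sr_together and the 8
        bipolar items item1..item8 (any may be NaN for missing responses).
    log : concatenated delivery log over all couples.
    schedules : mapping couple -> :class:`PhaseSchedule`.
    groups : optional mapping couple -> group label for group dummies.
    planned : optional frame couple, member, day, planned (0/1).

    Device outcomes from non-compliant days are set missing.  ``time_c`` is
    centered per 7 days over study days; ``wear_c`` is grand-mean centered
    over rows with an observed device outcome (model-level recentering over
    each fit's complete cases is applied by the estimators' wrappers).
    """
    design = design or TrialDesign()
    n_days = design.n_days

    dev = daily_device.copy()
    if "compliant" in dev.columns:
        dev["y_device"] = dev["mvpa_min"].where(dev["compliant"].astype(bool))
    elif "y_device" not in dev.columns:
        raise ValueError("daily_device needs either compliant+mvpa_min or y_device")
    dev = dev[["couple", "member", "day", "y_device", "wear_min"]]

    key = ["couple", "member", "day"]
    for name, frame in (("daily_device", dev), ("diary", diary)):
        if frame.duplicated(key).any():
            raise ValueError(f"duplicate (couple, member, day) rows in {name}")

    diary = diary.copy()
    diary["y_self"] = diary["sr_alone"] + diary["sr_together"]
    item_cols = [f"item{i}" for i in range(1, 9)]
    if set(item_cols) <= set(diary.columns):
        items = diary[item_cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            diary["barriers"] = np.where(
                np.isnan(items).any(axis=1), np.nan, np.maximum(-items, 0).sum(axis=1)
            )
            diary["facilitators"] = np.where(
                np.isnan(items).any(axis=1), np.nan, np.maximum(items, 0).sum(axis=1)
            )
    else:
        diary["barriers"] = diary.get("barriers", np.nan)
        diary["facilitators"] = diary.get("facilitators", np.nan)
    diary = diary[key + ["y_self", "barriers", "facilitators"]]

    rows = []
    for couple, schedule in schedules.items():
        coded = _coded_treatments(log[log["couple_id"] == couple], n_days)
        coded["couple"] = couple
        rows.append(coded)
    treat = pd.concat(rows, ignore_index=True)

    table = treat.merge(dev, on=key, how="left").merge(diary, on=key, how="left")

    if planned is not None:
        table = table.merge(planned[key + ["planned"]], on=key, how="left")
        table["planned"] = table["planned"].fillna(0).astype(int)
    else:
        table["planned"] = 0

    phase = {
        (c, d): int(s.phase(d) == "intervention")
        for c, s in schedules.items()
        for d in range(1, n_days + 1)
    }
    skilled = {c: s.skilled_support_day for c, s in schedules.items()}
    table["phase"] = [phase[(c, d)] for c, d in zip(table["couple"], table["day"])]
    table["skilled_support"] = [
        int(d >= skilled[c]) for c, d in zip(table["couple"], table["day"])
    ]
    table["weekend"] = [int(design.is_weekend(d)) for d in table["day"]]
    table["time_c"] = (table["day"] - table["day"].mean()) / 7.0

    if groups:
        labels = sorted(set(groups.values()))
        table["group"] = table["couple"].map(groups)
        for g in labels[1:]:  # first label is the reference category
            table[f"group_{g}"] = (table["group"] == g).astype(int)

    observed_dev = table["y_device"].notna()
    table["wear_c"] = table["wear_min"] - table.loc[observed_dev, "wear_min"].mean()

    sort_cols = ["couple", "member", "day"]
    return table.sort_values(sort_cols).reset_index(drop=True)
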