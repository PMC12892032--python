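"""Accelerometer preprocessing: wear-time detection and daily MVPA classification.

Minute-level vector-magnitude (VM) counts from a wrist-worn device are turned
into one daily summary per person-day: minutes of moderate-to-vigorous
physical activity (MVPA), wear minutes, and a wear-compliance flag.

Wear time uses the Choi non-wear rule on 1-minute epochs: a non-wear interval
is at least 90 consecutive minutes of zero counts, tolerating up to 2
consecutive non-zero "spike" minutes when each spike is flanked on both sides
by at least 30 minutes of zeros.  MVPA minutes are worn, awake minutes whose
VM count strictly exceeds the cut-point (default 2690 counts per minute).
Days with under 600 worn minutes (10 h) are flagged non-compliant and their
outcome is treated as missing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MinuteCounts",
    "DailyDeviceSummary",
    "choi_wear_mask",
    "sleep_window_mask",
    "daily_device_mvpa",
    "summarize_minute_csv",
    "CUTPOINT_CPM",
    "MIN_WEAR_MINUTES",
]

CUTPOINT_CPM = 2690
MIN_WEAR_MINUTES = 600  # 10 hours

# Choi et al. window parameters (published defaults)
CHOI_MIN_NONWEAR = 90
CHOI_SPIKE_TOLERANCE = 2
CHOI_FLANK_ZEROS = 30


@dataclass(frozen=True)
class MinuteCounts:
    """One person-day of per-minute VM counts.

    ``minute_of_day`` must be strictly increasing with 1-minute spacing (a
    gap is an error: no imputation is attempted); counts are non-negative.
    """

    couple: int
    member: int
    day: int
    minute_of_day: np.ndarray  # 0..1439
    vm_counts: np.ndarray

    def __post_init__(self):
        mod = np.asarray(self.minute_of_day, dtype=int)
        counts = np.asarray(self.vm_counts)
        if mod.shape != counts.shape or mod.ndim != 1:
            raise ValueError("minute_of_day and vm_counts must be aligned 1-d arrays")
        if len(mod) and (mod.min() < 0 or mod.max() > 1439):
            raise ValueError("minute_of_day out of range [0, 1439]")
        if np.any(np.diff(mod) != 1):
            raise ValueError("timestamps must be strictly increasing at 1-minute spacing (gap found)")
        if np.any(counts < 0):
            raise ValueError("vm_counts must be non-negative")
        object.__setattr__(self, "minute_of_day", mod)
        object.__setattr__(self, "vm_counts", np.asarray(counts, dtype=float))


@dataclass(frozen=True)
class DailyDeviceSummary:
    couple: int
    member: int
    day: int
    mvpa_min: int
    wear_min: int
    compliant: bool
    awake_mask_applied: bool


def _zero_runs(is_zero: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode: list of (start, length, run_is_zero)."""
    runs = []
    n = len(is_zero)
    i = 0
    while i < n:
        j = i
        while j < n and is_zero[j] == is_zero[i]:
            j += 1
        runs.append((i, j - i, bool(is_zero[i])))
        i = j
    return runs


def choi_wear_mask(counts: MinuteCounts) -> np.ndarray:
    """Boolean worn-mask per minute under the Choi non-wear rule.

    Zero runs are merged across tolerated spikes (non-zero runs of length
    <= 2 with >= 30 min of zeros immediately on each side); a merged segment
    of total length >= 90 min is non-wear, everything else is worn.
    """
    counts_arr = counts.vm_counts
    n = len(counts_arr)
    worn = np.ones(n, dtype=bool)
    if n == 0:
        return worn
    runs = _zero_runs(counts_arr == 0)
    # Walk runs, accumulating a candidate non-wear segment of zero runs
    # bridged by tolerated spikes.
    idx = 0
    while idx < len(runs):
        start, length, is_zero = runs[idx]
        if not is_zero:
            idx += 1
            continue
        seg_start = start
        seg_len = length
        j = idx
        # try to extend across spikes
        while (
            j + 2 < len(runs)
            and not runs[j + 1][2]
            and runs[j + 1][1] <= CHOI_SPIKE_TOLERANCE
            and runs[j][1] >= CHOI_FLANK_ZEROS
            and runs[j + 2][1] >= CHOI_FLANK_ZEROS
        ):
            seg_len += runs[j + 1][1] + runs[j + 2][1]
            j += 2
        if seg_len >= CHOI_MIN_NONWEAR:
            worn[seg_start : seg_start + seg_len] = False
        idx = j + 1
    return worn


def sleep_window_mask(
    counts: MinuteCounts, sleep_start: int = 0, sleep_end: int = 360
) -> np.ndarray:
    """Awake mask: True outside the configured sleep window (default 00:00-06:00).

    This is a deliberately simple stand-in for algorithmic sleep detection:
    the analysis only needs awake minutes excluded, and the window is
    configurable per study.
    """
    mod = counts.minute_of_day
    asleep = (mod >= sleep_start) & (mod < sleep_end)
    return ~asleep


def daily_device_mvpa(
    counts: MinuteCounts,
    wear_mask: np.ndarray,
    awake_mask: np.ndarray | None = None,
    cutpoint: float = CUTPOINT_CPM,
) -> DailyDeviceSummary:
    """Daily MVPA and wear summary from masked minute counts.

    MVPA minutes are worn, awake minutes with VM count strictly above the
    cut-point.  Wear minutes count worn *awake* minutes; compliance requires
    at least :data:`MIN_WEAR_MINUTES` of them.
    """
    n = len(counts.vm_counts)
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if wear_mask.shape != (n,):
        raise ValueError("wear_mask is not aligned to the minute series")
    awake_applied = awake_mask is not None
    if awake_mask is None:
        awake_mask = np.ones(n, dtype=bool)
    else:
        awake_mask = np.asarray(awake_mask, dtype=bool)
        if awake_mask.shape != (n,):
            raise ValueError("awake_mask is not aligned to the minute series")
    usable = wear_mask & awake_mask
    wear_min = int(usable.sum())
    mvpa_min = int(np.sum(counts.vm_counts[usable] > cutpoint))
    return DailyDeviceSummary(
        couple=counts.couple,
        member=counts.member,
        day=counts.day,
        mvpa_min=mvpa_min,
        wear_min=wear_min,
        compliant=wear_min >= MIN_WEAR_MINUTES,
        awake_mask_applied=awake_applied,
    )


def summarize_minute_csv(
    minutes: pd.DataFrame,
    cutpoint: float = CUTPOINT_CPM,
    sleep_start: int = 0,
    sleep_end: int = 360,
) -> pd.DataFrame:
    """Run the full pipeline over a long minute-level table.

    ``minutes`` needs columns couple, member, day, minute_of_day, vm_counts.
    Wear detection is applied first, then the awake window.  Returns one row
    per person-day: couple, member, day, mvpa_min, wear_min, compliant.
    """
    required = {"couple", "member", "day", "minute_of_day", "vm_counts"}
    missing = required - set(minutes.columns)
    if missing:
        raise ValueError(f"minute table missing columns: {sorted(missing)}")
    out = []
    for (couple, member, day), grp in minutes.groupby(["couple", "member", "day"], sort=True):
        grp = grp.sort_values("minute_of_day")
        mc = MinuteCounts(
            couple=couple,
            member=member,
            day=day,
            minute_of_day=grp["minute_of_day"].to_numpy(),
            vm_counts=grp["vm_counts"].to_numpy(),
        )
        worn = choi_wear_mask(mc)
        awake = sleep_window_mask(mc, sleep_start, sleep_end)
        s = daily_device_mvpa(mc, worn, awake, cutpoint)
        out.append(
            {"couple": s.couple, "member": s.member, "day": s.day,
             "mvpa_min": s.mvpa_min, "wear_min": s.wear_min, "compliant": s.compliant}
        )
    return pd.DataFrame(out)
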