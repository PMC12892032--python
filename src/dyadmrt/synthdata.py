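"""Synthetic dyadic-trial generator.

Simulates complete trials — couple-level group allocation, planned-activity
calendars, daily JITAI randomization, and person-day outcomes — with the
statistical structure the estimators assume:

* device MVPA = fixed part (baseline, phase, actor/partner JITAI indicators
  on their target days incl. lags, centered time, wear-time deviation)
  + couple-level random effects (intercept, phase, time, wear; shared by both
  members — partners are indistinguishable) + an AR(1) residual per member
  with optional same-day cross-partner innovation correlation;
* self-reported MVPA = a scaled copy of the latent device outcome plus a
  person-level reporting bias and day-level noise, tuned so the empirical
  between-/within-person correlations with device MVPA sit near the observed
  0.57 / 0.46;
* independent (MCAR) missingness per outcome.

Minute-level count series realizing a daily total are produced by
:func:`generate_minute_counts` for exercising the accelerometer pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import features
from .accel import CUTPOINT_CPM, MinuteCounts
from .design import (
    TrialDesign,
    allocate_groups,
    phase_schedule,
    planning_days,
    randomize_jitais,
)

__all__ = [
    "SimConfig",
    "TrueParams",
    "simulate_trial",
    "generate_minute_counts",
    "apply_missingness",
    "scenario_proximal",
    "scenario_null",
    "scenario_phase",
]

WEAR_MEAN = 840.0  # minutes/day
WEAR_SD = 90.0


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of one simulated trial.

    Effects are in minutes of daily MVPA.  ``sd_re`` holds the couple-level
    random-effect SDs in the order (intercept, phase, time, wear).  The
    self-report linkage (``sr_scale``, ``sr_bias_sd``, ``sr_noise_sd``) was
    calibrated once so that simulated device/self-report correlations match
    the observed between-person 0.57 and within-person 0.46.
    """

    n_couples: int = 38
    design: TrialDesign = field(default_factory=TrialDesign)
    beta0: float = 106.5
    beta_phase: float = 5.88
    beta_actor: float = 11.17
    beta_partner: float = 7.23
    beta_lag1: float = 0.0
    beta_lag2: float = 0.0
    beta_lag3: float = 0.0
    gamma_time: float = -1.05
    delta_wear: float = 0.15
    sd_re: tuple[float, float, float, float] = (24.30, 8.59, 4.21, 0.06)
    sigma: float = 49.89
    phi: float = 0.27
    rho_partner: float = 0.3
    sr_scale: float = 0.25
    sr_bias_sd: float = 9.0
    sr_noise_sd: float = 25.7
    miss_device: float = 0.113
    miss_self: float = 0.056
    plan_prob: float = 0.4
    truncate_at_zero: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.sigma < 0:
            problems.append("sigma must be >= 0")
        if not abs(self.phi) < 1:
            problems.append("|phi| must be < 1")
        if not abs(self.rho_partner) < 1:
            problems.append("|rho_partner| must be < 1")
        for name in ("miss_device", "miss_self", "plan_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must be in [0, 1]")
        if len(self.sd_re) != 4 or any(s < 0 for s in self.sd_re):
            problems.append("sd_re must be 4 non-negative SDs (intercept, phase, time, wear)")
        if self.n_couples < 1:
            problems.append("n_couples must be >= 1")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))
        object.__setattr__(self, "sd_re", tuple(float(s) for s in self.sd_re))


@dataclass(frozen=True)
class TrueParams:
    """Generating values of every estimable parameter, stored with a dataset."""

    beta0: float
    beta_phase: float
    beta_actor: float
    beta_partner: float
    beta_lag1: float
    beta_lag2: float
    beta_lag3: float
    gamma_time: float
    delta_wear: float
    sd_intercept: float
    sd_phase: float
    sd_time: float
    sd_wear: float
    sigma: float
    phi: float
    rho_partner: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrueParams":
        return cls(**json.loads(text))

    @classmethod
    def from_config(cls, config: SimConfig) -> "TrueParams":
        return cls(
            beta0=config.beta0,
            beta_phase=config.beta_phase,
            beta_actor=config.beta_actor,
            beta_partner=config.beta_partner,
            beta_lag1=config.beta_lag1,
            beta_lag2=config.beta_lag2,
            beta_lag3=config.beta_lag3,
            gamma_time=config.gamma_time,
            delta_wear=config.delta_wear,
            sd_intercept=config.sd_re[0],
            sd_phase=config.sd_re[1],
            sd_time=config.sd_re[2],
            sd_wear=config.sd_re[3],
            sigma=config.sigma,
            phi=config.phi,
            rho_partner=config.rho_partner,
        )


# ---------------------------------------------------------------------------
# Named study scenarios
# ---------------------------------------------------------------------------


def scenario_proximal(**overrides) -> SimConfig:
    """Proximal-effect calibration scenario: actor/partner JITAI effects at the
    observed magnitudes, no phase or lag effects, so the proximal-effect model's
    mean structure matches the generator."""
    base = SimConfig(beta_phase=0.0, beta_actor=11.17, beta_partner=7.23)
    return replace(base, **overrides)


def scenario_null(**overrides) -> SimConfig:
    """Null scenario: all intervention effects zero, noise structure retained."""
    base = SimConfig(beta_phase=0.0, beta_actor=0.0, beta_partner=0.0)
    return replace(base, **overrides)


def scenario_phase(**overrides) -> SimConfig:
    """Intervention-phase recovery scenario: the mixed model's generating values
    (phase effect, trend, wear slope, random-effect SDs, sigma, phi) with no
    JITAI effects and no cross-partner residual correlation, matching the
    structure of the fitted phase model."""
    base = SimConfig(
        beta_actor=0.0, beta_partner=0.0, beta_phase=5.88, rho_partner=0.0
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------


def _simulate_residuals(rng, n_days, sigma, phi, rho):
    """(2, n_days) stationary AR(1) residuals with same-day innovation corr rho.

    With jointly correlated innovations the stationary same-day cross-partner
    residual correlation equals rho as well.
    """
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    z = rng.standard_normal((n_days, 2)) @ chol.T  # (day, member)
    e = np.empty((n_days, 2))
    e[0] = sigma * z[0]
    scale = sigma * np.sqrt(1.0 - phi**2)
    for t in range(1, n_days):
        e[t] = phi * e[t - 1] + scale * z[t]
    return e.T


def _planned_days(rng, schedule, design, plan_prob):
    """Member-specific planned-activity days drawn around each planning session."""
    interv = set(schedule.intervention_days())
    sessions = planning_days(schedule, design)
    planned = {1: set(), 2: set()}
    for q in sessions:
        for m in (1, 2):
            for d in range(q + 1, q + 8):
                if d in interv and d <= design.n_days and rng.random() < plan_prob:
                    planned[m].add(d)
    return planned


def simulate_trial(config: SimConfig, return_raw: bool = False):
    """Simulate one full trial.

    Returns ``(table, log, params)`` where ``table`` is an analysis-ready
    person-day frame (2 rows per couple-day), ``log`` the concatenated
    delivery log and ``params`` the :class:`TrueParams` sidecar.  Everything
    is deterministic given ``config.seed``.

    With ``return_raw=True`` a fourth element carries the pre-assembly source
    tables (daily device summary, diary with the 8 bipolar items and the
    alone/together self-report split, planned-day indicators) so the feature
    assembly stage can be exercised end to end on simulated data.
    """
    design = config.design
    n_days = design.n_days
    rng = np.random.default_rng(config.seed)

    couple_ids = list(range(1, config.n_couples + 1))
    groups = allocate_groups(couple_ids, seed=int(rng.integers(2**31)), groups=design.groups)

    time_c = (np.arange(1, n_days + 1) - (n_days + 1) / 2.0) / 7.0
    days = np.arange(1, n_days + 1)
    weekend = np.array([int(design.is_weekend(d)) for d in days])
    schedules = {g: phase_schedule(g, design) for g in set(groups.values())}
    phase_by_group = {
        g: np.array([int(s.phase(d) == "intervention") for d in days])
        for g, s in schedules.items()
    }

    logs = []
    chunks = []  # one dict of column arrays per member series
    for couple in couple_ids:
        group = groups[couple]
        schedule = schedules[group]
        planned = _planned_days(rng, schedule, design, config.plan_prob)
        log = randomize_jitais(
            schedule, design, planned, seed=int(rng.integers(2**31)), couple_id=couple
        )
        logs.append(log)

        phase = phase_by_group[group]
        u = rng.normal(0.0, 1.0, size=4) * np.asarray(config.sd_re)
        resid = _simulate_residuals(rng, n_days, config.sigma, config.phi, config.rho_partner)
        sr_bias = rng.normal(0.0, config.sr_bias_sd, size=2)

        for m in (1, 2):
            coded = features.code_targets(log, m, n_days)
            cols = {c: coded[c].to_numpy() for c in coded.columns}
            for base in ("jitai_actor", "jitai_partner"):
                lags = features.lag_indicators(coded[base], max_lag=3)
                for k in (1, 2, 3):
                    cols[f"{base}_lag{k}"] = lags[f"lag{k}"].to_numpy()
            wear = np.clip(rng.normal(WEAR_MEAN, WEAR_SD, size=n_days), 0.0, 1440.0)
            wear_dev = wear - WEAR_MEAN
            lag_part = (
                config.beta_lag1 * cols["jitai_actor_lag1"]
                + config.beta_lag2 * cols["jitai_actor_lag2"]
                + config.beta_lag3 * cols["jitai_actor_lag3"]
            )
            mean = (
                config.beta0
                + config.beta_phase * phase
                + config.beta_actor * cols["jitai_actor"]
                + config.beta_partner * cols["jitai_partner"]
                + lag_part
                + config.gamma_time * time_c
                + config.delta_wear * wear_dev
                + u[0]
                + u[1] * phase
                + u[2] * time_c
                + u[3] * wear_dev
            )
            y_dev = mean + resid[m - 1]
            if config.truncate_at_zero:
                y_dev = np.maximum(y_dev, 0.0)
            y_self = (
                config.sr_scale * y_dev
                + sr_bias[m - 1]
                + rng.normal(0.0, config.sr_noise_sd, size=n_days)
            )
            items = rng.integers(-5, 6, size=(n_days, 8))
            chunks.append(
                {
                    "couple": np.full(n_days, couple),
                    "member": np.full(n_days, m),
                    "day": days,
                    **cols,
                    **{f"item{i + 1}": items[:, i] for i in range(8)},
                    "group": np.full(n_days, group, dtype=object),
                    "phase": phase,
                    "planned": np.isin(days, sorted(planned[m])).astype(int),
                    "time_c": time_c,
                    "wear_min": wear,
                    "wear_c": wear_dev,
                    "weekend": weekend,
                    "skilled_support": (days >= schedule.skilled_support_day).astype(int),
                    "y_device": y_dev,
                    "y_self": y_self,
                    "barriers": np.maximum(-items, 0).sum(axis=1),
                    "facilitators": np.maximum(items, 0).sum(axis=1),
                }
            )

    table = pd.DataFrame(
        {name: np.concatenate([c[name] for c in chunks]) for name in chunks[0]}
    )
    labels = sorted(set(design.groups))
    for g in labels[1:]:
        table[f"group_{g}"] = (table["group"] == g).astype(int)
    table = apply_missingness(
        table, config.miss_device, config.miss_self, seed=int(rng.integers(2**31))
    )
    table = table.sort_values(["couple", "member", "day"]).reset_index(drop=True)
    log = pd.concat(logs, ignore_index=True)

    item_cols = [f"item{i}" for i in range(1, 9)]
    raw = None
    if return_raw:
        key = ["couple", "member", "day"]
        daily_device = table[key + ["wear_min"]].copy()
        daily_device["mvpa_min"] = table["y_device"]
        # downstream, a missing device day presents as a wear-non-compliant day
        daily_device["compliant"] = table["y_device"].notna()
        diary = table[key + item_cols].copy()
        # fixed 60/40 alone/together split: only the sum is modeled
        diary["sr_alone"] = 0.6 * table["y_self"]
        diary["sr_together"] = 0.4 * table["y_self"]
        diary.loc[table["y_self"].isna(), item_cols] = np.nan
        planned = table[key + ["planned"]].copy()
        raw = {"daily_device": daily_device, "diary": diary, "planned": planned}
    table = table.drop(columns=item_cols)
    if return_raw:
        return table, log, TrueParams.from_config(config), raw
    return table, log, TrueParams.from_config(config)


def apply_missingness(daily: pd.DataFrame, miss_device: float, miss_self: float, seed: int):
    """Flag person-days missing completely at random, independently per outcome."""
    for rate, name in ((miss_device, "miss_device"), (miss_self, "miss_self")):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = daily.copy()
    n = len(out)
    out["miss_device"] = rng.random(n) < miss_device
    out["miss_self"] = rng.random(n) < miss_self
    out.loc[out["miss_device"], "y_device"] = np.nan
    out.loc[out["miss_self"], "y_self"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Minute-level realization
# ---------------------------------------------------------------------------


def generate_minute_counts(
    daily_true_mvpa: int,
    wear_windows,
    seed: int,
    couple: int = 0,
    member: int = 1,
    day: int = 1,
    sleep_end: int = 360,
) -> MinuteCounts:
    """Realize a daily MVPA total as a 1440-minute VM count series.

    Counts are zero outside the wear windows; exactly ``daily_true_mvpa``
    worn awake minutes get counts above the MVPA cut-point and every other
    worn minute gets a count in (0, cut-point], so the accelerometer pipeline
    recovers the daily total exactly on compliant days.  Wear windows are
    half-open minute intervals ``[start, stop)`` and should be at least a few
    minutes long (1-2 minute windows would be absorbed as non-wear spikes).
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(1440)
    worn = np.zeros(1440, dtype=bool)
    for start, stop in wear_windows:
        if not (0 <= start < stop <= 1440):
            raise ValueError(f"invalid wear window ({start}, {stop})")
        worn[start:stop] = True
    awake_worn = np.flatnonzero(worn & (np.arange(1440) >= sleep_end))
    daily_true_mvpa = int(daily_true_mvpa)
    if daily_true_mvpa < 0:
        raise ValueError("daily_true_mvpa must be non-negative")
    if daily_true_mvpa > len(awake_worn):
        raise ValueError(
            f"target MVPA of {daily_true_mvpa} min exceeds the {len(awake_worn)} worn awake minutes"
        )
    worn_idx = np.flatnonzero(worn)
    counts[worn_idx] = rng.integers(1, CUTPOINT_CPM + 1, size=len(worn_idx))
    active = rng.choice(awake_worn, size=daily_true_mvpa, replace=False)
    counts[active] = rng.integers(CUTPOINT_CPM + 1, 8000, size=daily_true_mvpa)
    return MinuteCounts(
        couple=couple,
        member=member,
        day=day,
        minute_of_day=np.arange(1440),
        vm_counts=counts,
    )
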