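"""Orchestration: the trial's model menu, end-to-end analysis, and recovery runs.

``run_analysis`` fits the report's model menu on an analysis table: the
intervention-phase mixed model plus the proximal-effect (WCLS) models for
planning, actor/partner JITAIs, the type split, the timing split, and the
lagged model — each for the device-based and the self-reported outcome, with
an optional sensitivity covariate set (group, weekend, skilled support,
barriers, facilitators).

``recovery_experiment`` repeatedly simulates trials from a scenario and
re-estimates, summarizing per-parameter truth, mean estimate, bias, RMSE,
confidence-interval coverage and rejection rates.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .mlm import DyadicMixedAR1
from .synthdata import SimConfig, TrueParams, scenario_null, scenario_phase, scenario_proximal, simulate_trial
from .wcls import DyadicWCLS

__all__ = ["MODEL_MENU", "build_model", "run_analysis", "recovery_experiment", "SCENARIOS"]

MODEL_MENU = ("phase", "planning", "actor_partner", "type", "timing", "lags")

SENSITIVITY_COVARIATES = (
    "group_B",
    "group_C",
    "weekend",
    "skilled_support",
    "barriers",
    "facilitators",
)

SCENARIOS = {
    "default": SimConfig,
    "proximal": scenario_proximal,
    "null": scenario_null,
    "phase": scenario_phase,
}

_WCLS_TREATMENTS = {
    "planning": ("planned",),
    "actor_partner": ("jitai_actor", "jitai_partner"),
    "type": ("crossover_actor", "crossover_partner", "joint"),
    "timing": (
        "timing_planning_actor",
        "timing_activity_actor",
        "timing_evening_actor",
        "timing_planning_partner",
        "timing_activity_partner",
        "timing_evening_partner",
    ),
    "lags": (
        "jitai_actor",
        "jitai_actor_lag1",
        "jitai_actor_lag2",
        "jitai_actor_lag3",
        "jitai_partner",
        "jitai_partner_lag1",
        "jitai_partner_lag2",
        "jitai_partner_lag3",
    ),
}

_WCLS_ONE_SIDED = {
    "planning": ("planned",),
    "actor_partner": ("jitai_actor", "jitai_partner"),
    "type": (),
    "timing": (),
    "lags": (),
}


def _controls(table, outcome, sensitivity):
    controls = ["time_c"]
    if outcome == "y_device":
        controls.append("wear_c")
    if sensitivity:
        controls += [c for c in SENSITIVITY_COVARIATES if c in table.columns]
    return controls


def build_model(
    model: str,
    table: pd.DataFrame,
    outcome: str,
    sensitivity: bool = False,
    jitai_prob: float = 0.5,
    ci_level: float = 0.90,
):
    """Construct the (unfitted) estimator for one menu entry and outcome.

    JITAI treatment terms center at the design randomization probability; the
    planning indicator is not day-randomized, so it centers at its empirical
    proportion with unit weight (an associational contrast).
    """
    if model not in MODEL_MENU:
        raise ValueError(f"unknown model {model!r}; menu: {MODEL_MENU}")
    controls = _controls(table, outcome, sensitivity)
    if model == "phase":
        fixed = ["phase"] + controls
        random = ["intercept", "phase", "time_c"] + (["wear_c"] if outcome == "y_device" else [])
        return DyadicMixedAR1(
            fixed=tuple(fixed),
            random=tuple(random),
            ar1=True,
            one_sided=("phase",),
            ci_level=ci_level,
            center=tuple(controls),
        )
    terms = _WCLS_TREATMENTS[model]
    treatments = {}
    for term in terms:
        if model == "planning":
            obs = table.dropna(subset=[outcome])[term]
            p_tilde = float(np.clip(obs.mean(), 0.01, 0.99))
        else:
            p_tilde = jitai_prob
        treatments[term] = p_tilde
    return DyadicWCLS(
        treatments=treatments,
        controls=tuple(controls),
        one_sided=_WCLS_ONE_SIDED[model],
        ci_level=ci_level,
    )


def run_analysis(
    table: pd.DataFrame,
    menu=MODEL_MENU,
    outcomes=("y_device", "y_self"),
    sensitivity: bool = False,
    jitai_prob: float = 0.5,
    ci_level: float = 0.90,
):
    """Fit every requested model for every outcome.

    Returns ``(tables, counts)``: a dict mapping ``"<model>__<outcome>"`` to
    the fit's summary frame, and a complete-case bookkeeping frame with the
    rows used per model.
    """
    tables = {}
    counts = []
    for model in menu:
        for outcome in outcomes:
            est = build_model(model, table, outcome, sensitivity, jitai_prob, ci_level)
            try:
                est.fit(table, outcome=outcome)
            except Exception as err:  # annotate with stage provenance
                raise RuntimeError(f"model {model!r} on outcome {outcome!r} failed: {err}") from err
            tables[f"{model}__{outcome}"] = est.summary()
            counts.append(
                {
                    "model": model,
                    "outcome": outcome,
                    "n_rows_used": est.n_rows_,
                    "n_rows_total": len(table),
                    "n_missing_outcome": int(table[outcome].isna().sum()),
                    "n_couples": est.n_couples_,
                }
            )
    return tables, pd.DataFrame(counts)


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------


def _truth_map(params: TrueParams, model: str) -> dict:
    if model == "phase":
        return {
            "intercept": params.beta0,
            "phase": params.beta_phase,
            "time_c": params.gamma_time,
            "wear_c": params.delta_wear,
            "sd_intercept": params.sd_intercept,
            "sd_phase": params.sd_phase,
            "sd_time_c": params.sd_time,
            "sd_wear_c": params.sd_wear,
            "sigma": params.sigma,
            "phi": params.phi,
        }
    if model == "actor_partner":
        return {"jitai_actor": params.beta_actor, "jitai_partner": params.beta_partner}
    raise ValueError(f"recovery is defined for models 'phase' and 'actor_partner', not {model!r}")


def _collect_estimates(est, model: str) -> dict:
    out = {}
    if model == "phase":
        for term in est.fixed_cols_:
            out[term] = {
                "estimate": float(est.fe_params_[term]),
                "lower": float(est.fe_conf_int_.loc[term, "lower"]),
                "upper": float(est.fe_conf_int_.loc[term, "upper"]),
                "p": float(est.fe_pvalues_[term]),
            }
        for term in est.random_cols_:
            out[f"sd_{term}" if term != "intercept" else "sd_intercept"] = {
                "estimate": float(est.re_sd_[term]),
                "lower": float(est.re_sd_conf_int_.loc[term, "lower"]),
                "upper": float(est.re_sd_conf_int_.loc[term, "upper"]),
                "p": np.nan,
            }
        out["sigma"] = {"estimate": est.sigma_, "lower": np.nan, "upper": np.nan, "p": np.nan}
        out["phi"] = {
            "estimate": est.phi_,
            "lower": est.phi_conf_int_[0],
            "upper": est.phi_conf_int_[1],
            "p": np.nan,
        }
    else:
        for term in est.treatments:
            out[term] = {
                "estimate": float(est.params_[term]),
                "lower": float(est.conf_int_.loc[term, "lower"]),
                "upper": float(est.conf_int_.loc[term, "upper"]),
                "p": float(est.pvalues_[term]),
            }
    return out


def recovery_experiment(
    config: SimConfig,
    reps: int,
    seed: int,
    model: str = "actor_partner",
    outcome: str = "y_device",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulate ``reps`` trials from ``config`` and refit ``model`` each time.

    Returns one row per recovered parameter: truth, mean estimate, bias,
    Monte-Carlo SE of the mean, RMSE, CI coverage at the estimator's nominal
    level, and the rejection rate of the reported test at ``alpha``.
    Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31, size=reps)
    records = []
    truth = None
    for r in range(reps):
        cfg = replace(config, seed=int(rep_seeds[r]))
        table, _, params = simulate_trial(cfg)
        if truth is None:
            truth = _truth_map(params, model)
        est = build_model(model, table, outcome, jitai_prob=cfg.design.jitai_prob)
        est.fit(table, outcome=outcome)
        for name, rec in _collect_estimates(est, model).items():
            records.append({"rep": r, "param": name, **rec})
    raw = pd.DataFrame(records)
    rows = []
    for name, grp in raw.groupby("param", sort=False):
        if name not in truth:
            continue
        tru = truth[name]
        estimates = grp["estimate"].to_numpy()
        cover = ((grp["lower"] <= tru) & (tru <= grp["upper"])).to_numpy()
        has_ci = np.isfinite(grp["lower"].to_numpy())
        pvals = grp["p"].to_numpy()
        rows.append(
            {
                "param": name,
                "truth": tru,
                "mean_estimate": float(estimates.mean()),
                "bias": float(estimates.mean() - tru),
                "mc_se": float(estimates.std(ddof=1) / np.sqrt(len(estimates)))
                if len(estimates) > 1
                else 0.0,
                "rmse": float(np.sqrt(np.mean((estimates - tru) ** 2))),
                "coverage": float(cover[has_ci].mean()) if has_ci.any() else np.nan,
                "rejection_rate": float((pvals[np.isfinite(pvals)] < alpha).mean())
                if np.isfinite(pvals).any()
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
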