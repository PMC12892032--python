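# Methods

## Trial structure and randomization

The simulated trial runs `n_days = 55` days (day 1 a Saturday). Couples are
block-randomized to three groups that share a first control week and differ in
when the intervention phase occurs: group A is in the intervention phase from
day 8 to day 55; group B from day 8 to 28, then control; group C is in control
until day 35 and in intervention from day 36. The nominal week plan totals 56
days, so the final block of each sequence is truncated by one day to end on
day 55. The skilled-support psychoeducation session is placed on the first
Saturday of each couple's own first intervention phase (day 8 for A/B, day 36
for C); weekly planning sessions fall on the Sundays inside the intervention
phase.

Each intervention-phase day, with probability `jitai_prob` (default 0.5, a
configurable design parameter) one JITAI is drawn uniformly from the catalogue
entries that are *feasible* that day; otherwise the day is logged as an
embedded control day. Feasibility and the mapping from delivery day to
target days are timing-specific:

* `before_activity` targets the delivery day itself and is feasible only when
  that day is a planned-activity day for the targeted member;
* `evening` targets the member's next planned day strictly after delivery
  (reflection ahead of the next occasion);
* `before_planning` targets every planned day in the week following the next
  planning session.

These rules are one concrete reading of "the effect may fall on a later day
the couple intended to be active"; they are explicit, configurable, and logged
per delivery so downstream coding never re-derives them. Joint JITAIs target
both members; because member-specific timing rules can produce different
target days per member, joint deliveries assign the *union* of the two
members' target-day sets to both, which keeps the coding property "a joint
JITAI targets both the actor's and the partner's MVPA on the same days"
exactly true. Cross-over JITAIs are sent to one member and may target either
the recipient's own activity or the partner's; the default catalogue contains
both directions at every timing, plus joint entries, all equally weighted.

## The generative model

For member `m` of couple `j` on day `t`, device MVPA (minutes/day) is

    Y = β₀ + β_phase·phase + β_actor·A_actor + β_partner·A_partner
        + Σ_k β_lag_k·A_actor(t−k) + γ_time·time_c + δ_wear·(wear − 840)
        + u_j0 + u_j1·phase + u_j2·time_c + u_j3·(wear − 840) + e_mjt

with `time_c = (day − 28)/7` (per-week units, centered on the study middle),
wear time drawn N(840, 90²) minutes truncated to [0, 1440], couple random
effects `u_j ~ N(0, diag(sd_re²))` shared by both members (partners are
indistinguishable by construction), and residuals that are stationary AR(1)
within member with coefficient `phi` and residual SD `sigma`; the two members'
innovations are correlated `rho_partner`, which makes the stationary same-day
cross-partner residual correlation equal `rho_partner` as well (and the
cross-lagged correlation `rho·φ^d`, slightly richer than the same-day-only
structure the mixed model fits).

Default generating values are the study's fitted magnitudes: β₀ = 106.5,
β_phase = 5.88, β_actor = 11.17, β_partner = 7.23, γ_time = −1.05,
δ_wear = 0.15, sd_re = (24.30, 8.59, 4.21, 0.06), σ = 49.89, φ = 0.27,
lag effects 0, `rho_partner = 0.3` (no cross-partner correlation is reported
for the real data; 0.3 is a plausible stress value for the couple-clustered
estimators). Self-report MVPA is a noisy linear readout of the latent device
outcome, `Y_self = 0.25·Y + b_i + ε`, with person bias SD 9.0 and day noise SD
25.7; these three linkage values were calibrated once so that the simulated
between-person and within-person device/self-report correlations sit at the
observed 0.57 and 0.46. Missingness is MCAR at 11.3% (device) and 5.6%
(self-report) — the observed proportions — because complete-case estimation,
which the analysis uses throughout, is unbiased only under MCAR; MAR
mechanisms are left as configuration extensions.

Outcomes are Gaussian without a floor by default, which makes parameter
recovery exact; `truncate_at_zero` clips at 0 and documents the resulting
bias. Real MVPA is non-negative, right-skewed, and its missingness is surely
not MCAR; passing recovery tests therefore demonstrates estimator correctness
under the assumed model, not robustness to those real-data features.

Three named scenarios pin the calibration experiments: `scenario_proximal`
(actor/partner effects on, phase and lag effects zero, so the proximal-effect
model's mean structure matches the generator), `scenario_null` (all effects
zero; for test size), and `scenario_phase` (the phase-model generating values
with JITAI effects and `rho_partner` zero, matching the structure of the
fitted phase model). Matching generator and model structure is deliberate:
these runs measure calibration of the estimators, not robustness to
misspecification.

## Minute-level realization and preprocessing

`generate_minute_counts` realizes a daily total as a 1440-minute count
series: zeros outside wear windows, counts in (0, 2690] on ordinary worn
minutes, and counts above 2690 on exactly the target number of worn awake
minutes, so the accelerometer pipeline recovers the daily total exactly on
compliant days. Wear detection follows the published Choi rule (≥90-min zero
runs, ≤2-min spikes tolerated when flanked by ≥30 min of zeros on both
sides; parameters fixed at those defaults). The awake filter is a simple
configurable sleep window (default 00:00–06:00 excluded) rather than an
algorithmic sleep detector — the analysis only needs awake minutes excluded.
Wear detection runs first, then the awake mask; the order is configurable.
The cut-point comparison is strict (`> 2690` counts/min), and compliance
requires ≥600 worn awake minutes; non-compliant days yield a missing device
outcome. Days are calendar-midnight bounded, and timestamp gaps raise rather
than impute.

## WCLS estimator

Treatment indicators enter centered, `A_k − p̃_k`; controls enter uncentered
and (matching the analysis convention) are grand-mean centered over each
fit's complete-case rows. Row weights multiply the per-term ratio
`p̃^A(1−p̃)^{1−A} / p^A(1−p)^{1−A}`. Defaults: JITAI terms center at the
design randomization probability with `p = p̃` (unit weights); the planning
indicator is not day-randomized, so it centers at its empirical proportion
with unit weight and is reported as an associational contrast. Availability
is taken as 1 for every person-day. Both members' rows enter the fit;
randomization is at couple level, so weights are shared within a couple-day
and the variance is clustered by couple with the Mancl–DeRouen correction
(`(I − H_jj)^{-1}`-adjusted couple residuals in the meat). Inference uses
`t(df = n_couples − n_parameters)`; hypothesized effects are tested
upper-tailed, everything else two-tailed; intervals default to 90%.

Degenerate inputs: couples whose rows are all incomplete are dropped with a
warning; zero-variance columns are dropped with a warning rather than
silently regularized; remaining rank deficiency raises an error naming the
collinear columns; fewer than two couples, non-binary treatment columns, and
`p ∈ {0, 1}` raise.

## Mixed model

Per-couple marginal covariance `V_j = Z_j G Z_j' + R_j` with diagonal `G`
(the study reports only SDs, never covariances, so an unstructured `G` is out
of scope) and `R_j = σ²·AR1(φ)` within each member's day series, optionally
plus a same-day cross-partner correlation ρ (excluded by default, matching
the reported model; `rho_partner_free=True` frees it). REML is maximized over
an unconstrained parameterization — log variance *ratios* `log(τ_k/σ)` and
`atanh(φ)`, with σ² profiled out analytically — by L-BFGS-B from three
deterministic starts (objective tolerance 1e-8, max 500 iterations; the best
of the three local fits is kept, and non-convergence from every start raises
with the trace). Variance components at the boundary (→0) are reported, not
treated as errors.

Because an AR(1) process is Markov, each member's residual precision is
tridiagonal even with missing days (correlation `φ^d` across a gap of `d`
days), so the implementation whitens each series in O(T) and applies a
low-rank Woodbury update for the random effects; all member series are padded
into rectangular arrays and the per-couple 4×4 solves are batched. The
whitened path is checked against a dense multivariate-normal evaluation in
the tests to 1e-6. With ρ free the couple covariance loses this structure and
a dense per-couple Cholesky path is used.

Fixed effects follow by GLS at the optimum with covariance `σ̂²(ΣX'V₀⁻¹X)⁻¹`
and a containment-style `df = n_rows − n_couples − (n_fixed − 1)` (which
reproduces the conventional df arithmetic for this design: 3706 − 38 − 3 =
3665 at full data; exact replication of any particular software's df rules is
a non-goal). Random-effect SDs carry delta-method SEs from a numerical
Hessian of the REML objective on the log-SD/atanh scale, with lognormal-scale
confidence intervals (hence asymmetric bounds) and z = estimate/SE.

## Simulation checks and their sizes

The calibration experiments use 500 replicates for interval coverage of the
actor proximal effect (38 couples × 55 days per replicate), 1000 replicates
for the size of the upper-tailed α = 0.05 test under the null, and 200
replicates for mixed-model parameter recovery; these sizes put the
Monte-Carlo error comfortably below the tolerances being checked while
keeping the full suite fast. Coverage at the nominal 90% level lands within
±3 percentage points and the test size within 5% ± 1.5%.

One recovery caveat is intrinsic rather than numerical: REML recovers the
random-effect *variances* essentially unbiasedly, but the reported SDs are
square roots, and for weakly identified components Jensen's inequality
depresses the mean reported SD by about `Var(τ̂²)/(8τ³)` — roughly 1.1
minutes for the phase slope SD (per-replicate RMSE ≈ 4.4 around a truth of
8.59 at 38 couples) and a few tenths of a minute for the intercept SD. The
test suite documents both facts: the SD-scale means for those components can
fall outside 2 Monte-Carlo SEs of the generating values, while the
variance-scale recovery check passes.

## Known limitations

* The JITAI selection process is simulated as uniform over feasible catalogue
  entries at a single configurable daily probability; any state-dependent
  selection used in a real deployment would need a custom catalogue/probability
  configuration.
* The generator's barriers/facilitators items are iid and unrelated to the
  outcome, so sensitivity-covariate fits exercise the plumbing, not
  confounding.
* Whether group C's skilled-support session precedes or coincides with its
  late intervention phase is undocumented; it is placed at the first Saturday
  of that phase.
* Time-varying (moderated) proximal effects, availability-weighted estimands,
  Kenward–Roger/Satterthwaite df, and distinguishable-dyad parameterizations
  are out of scope.
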