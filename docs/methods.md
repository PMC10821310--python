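# Methods

## Model structure

A deterministic three-state Markov cohort model (progression-free [PFS],
progressive disease [PD], dead) for first-line serplulimab + cisplatin/
5-fluorouracil (CF) versus CF in PD-L1-positive advanced esophageal
squamous cell carcinoma.  The whole cohort starts in PFS.  Cycles are 14
days (0.4600 months at 30.4375 days/month); the horizon is 10 years, i.e.
`ceil(120 / 0.4600) = 261` cycles.  Death is absorbing.  With the
published Weibull inputs, more than 95% of the cohort is dead by the
horizon in every stratum and arm, so the horizon effectively captures
lifetime costs and effects.

Per cycle, the death probability is the conditional per-cycle event
probability of the overall-survival (OS) curve, `1 − S_os(t)/S_os(t−u)`,
applied to both alive states; the PFS→PD probability is the excess of the
PFS curve's exit probability over the death probability, clamped at zero.
This construction makes the trace algebraically identical to
partitioned-survival membership `(S_pfs, S_os − S_pfs, 1 − S_os)` at
every cycle boundary, which is the only construction consistent with a
"Markov model" parameterized directly by OS and PFS curves.  The identity
holds until the two conditional probabilities cross; for some parameter
sets (PFS shape < 1, OS shape > 1) they cross deep in the tail, where
memberships are ~1e−9 and the clamp (counted and reported on the trace)
takes over.  Clamping guarantees memberships stay non-negative and
conserve to 1 within 1e−12.

## Survival inputs and the time-scale convention

Both arms' OS and PFS are Weibull, `S(t) = exp(−λ t^γ)`, with the scale
and shape pairs of the published input table, stratified by PD-L1
combined positive score (overall, 1≤CPS<10, CPS≥10).  On a monthly time
axis these parameters imply median OS of 16.5 / 12.2 months
(intervention / comparator) and median PFS of 6.7 / 4.5 months, tracking
the trial medians (15.3 / 11.8 and 5.8 / 5.3) within 15%, which fixes
the parameters' unit as months.

The time fed to the curves inside the cohort engine is a separate
convention.  The published totals (≈0.87 / 0.60 discounted life-years)
are only reproducible when the transition formula is evaluated at the
cycle *index* (t = k, u = 1) — the `_stage` convention of the commercial
tool this class of model is usually built in — while calendar time
(k × 0.46 months) is used for life-years and discounting.  Evaluating
the curves in calendar months instead roughly doubles survival time and
every total.  The engine therefore defaults to
`transition_time_scale="cycle"` and exposes `"months"` as an alternative
so the consequence of the convention can be quantified; the base-case
ICER is relatively insensitive to it (both costs and QALYs stretch
together) but arm-level totals are not.

## Fitting digitized Kaplan–Meier points

The fitting stage consumes (time, survival) point sets as produced by
graph digitizers, not individual patient data.  Five families are
supported (exponential, Weibull, log-logistic, log-normal, Gompertz with
hazard a·e^{bt}).  The Weibull is fitted by ordinary least squares on the
complementary-log-log transform `log(−log S) = log λ + γ log t`, which is
exactly linear, so noise-free points are recovered to machine precision;
the exponential by one-parameter regression of −log S on t through the
origin; the other families by nonlinear least squares on the survival
scale (Levenberg–Marquardt, cloglog-based starting values).  Points with
S = 0 or 1 are dropped before fitting (log undefined; noted in the fit
result).  AIC/BIC use the Gaussian residual likelihood on the survival
scale, `n·log(SSE/n) + penalty·(k+1)` with k the number of distribution
parameters plus one for the residual variance, so criteria are comparable
across families; selection is minimal AIC, ties broken by BIC then family
order.  Pseudo-individual-patient-data reconstruction and
interval-censored maximum likelihood are deliberately out of scope.

## Costing conventions

All costs in US dollars (the source prices were converted at $1 =
¥7.0559).  Per-cycle while in PFS: serplulimab $198 (capped at 2 years =
52 cycles, intervention arm only), cisplatin $12 (8 cycles), 5-FU $127
(12 cycles), administration $12 whenever any first-line drug is given,
plus laboratory $53 and imaging $162.  While in PD: the second-line
proportion (0.38 intervention / 0.52 comparator — the trial-reported
shares; the input table prints the pair transposed) receives paclitaxel
$180 + administration, the remainder best supportive care $70/cycle,
with no duration cap.  One-time: PD-L1 test $86 and the lump
adverse-event cost ($65 / $60) at model start; terminal care $1,402 per
death in the cycle it occurs.  Only grade ≥3 adverse events with
incidence ≥5% carry costs and disutilities; their aggregate disutility
(Σ incidence × decrement: 0.0403 / 0.0364 QALY) is subtracted once at
model start, reflecting that these events concentrate under early
first-line therapy.  Drug costs scale linearly with body weight (per-kg
dosing: serplulimab) or body surface area (per-m² dosing: cisplatin,
5-FU, paclitaxel) relative to the 65 kg / 1.72 m² reference patient, so
the printed prices apply unchanged at baseline and the scaling matters
only when weight/BSA are perturbed.

Routine monitoring (laboratory + imaging) is charged **in PFS only** by
default.  The source does not state whether monitoring continues after
progression; calibration against the published arm-level totals
(~$7,241 / $4,078) identifies the monitoring-in-PFS-only convention
(giving ~$8,063 / $4,803) — charging monitoring in PD as well overshoots
both arms by ~50–65%.  The alternative remains available via
`EconSettings.monitoring_in_pd`.

Half-cycle correction is off by default (state membership evaluated at
cycle start); a trapezoid variant is exposed as a flag because it shifts
LY/QALY by up to half a cycle.

Discounting is discrete annual, `1/(1+r)^t` with t in years at cycle
start, r = 5% (range 0–8%).

## Incremental comparison

ICER = ΔCost/ΔQALY (and per LY), with dominance flags instead of ratios
when the signs disagree, and an explicit "undefined" status when
ΔQALY = 0 ≠ ΔCost.  Net monetary benefit `NMB = WTP·QALY − Cost` is used
for acceptability curves; the intervention is preferred by NMB at a given
WTP exactly when it is dominant or its ICER is below that WTP.

## Sensitivity analyses

**One-way**: every input-table row with a printed range (±20% of
baseline) plus the discount rate over 0–0.08 is set to its low and high
bound in turn, all else at baseline; results are ordered by ICER spread
for the tornado.  An end that would violate the utility ordering
(u_PD > u_PFS) is clamped to validity and flagged.  Utility of PFS and
the serplulimab price dominate the tornado, matching the source's
qualitative account.

**Probabilistic**: 10,000 seeded draws by default.  Distributions follow
the input table — beta for probabilities, incidences, proportions,
utilities and disutilities; gamma for costs; normal for weight and body
surface area; uniform for the discount rate — parameterized by method of
moments with SE = (max − min)/(2·1.96); an infeasible beta variance falls
back to uniform on the range (logged).  Draws are taken in a fixed
canonical order (costs, incidences, utilities, disutilities, weight, BSA,
discount, proportions) from one seeded generator, so runs are
bit-reproducible; invalid draws (u_PD > u_PFS, non-positive weight/BSA)
are redrawn and counted.  The Weibull survival parameters are **not**
varied: the published input table assigns them no distribution.  A
consequence, verified numerically, is that the incremental QALY is nearly
deterministic (sd ≈ 0.013 around 0.14) and essentially every draw falls
below the $36,438/QALY threshold, so this package's PSA acceptance
probability is ≈100%, not the ~74% the source reports; reproducing a
materially lower acceptance would require uncertainty the printed inputs
do not contain (e.g. survival-parameter uncertainty or patient-level
simulation).  This discrepancy is reported as-is rather than hidden by
re-parameterization.

**Price threshold**: bisection on a multiplier of the serplulimab
per-cycle price until the ICER is within $1/QALY of the WTP.  The ICER is
strictly increasing in the multiplier (ΔCost is linear in it, ΔQALY
constant), so bisection is exact; the model reaches $36,438/QALY at
≈1.97× (~$389/cycle).

**Subgroups**: defined only by OS and PFS hazard ratios; the comparator
keeps the baseline fitted curves and the intervention's are derived by
proportional hazards S^HR (closed-form for Weibull via λ·HR).  With the
overall-trial hazard ratios (0.68, 0.60) the subgroup ICER lands within
~21% of the directly fitted base case, an internal-consistency check on
the mechanism.  No numeric subgroup targets exist in the main source
tables.

## Synthetic data

`generate_km_points` emulates digitization: truth-curve survival plus
additive Gaussian error (default sd 0.01 on the survival scale), clipped
to (0, 1], monotonized by running minimum, and with PFS clipped to never
exceed OS.  It reproduces the statistical structure the fitter assumes —
smooth parametric truth plus small reading error — but not real
digitization artifacts (step functions at event times, censoring-induced
bias, correlated errors along a curve).  Passing recovery tests therefore
demonstrates correctness of the fitting pipeline, not robustness to every
real-world digitization pathology.

## Numerical choices and degenerate inputs

Survival underflow deep in the tail is treated as S = 0 and the
conditional transition probability as 1; memberships are clipped against
−1e−300-scale round-off.  Bisection tolerance for the price threshold is
$1/QALY; fit failures (too few usable points, non-positive fitted shape)
raise typed errors with messages.  Configuration validation collects
every violation in one pass and reports parameter names.

## Problem sizes

The default test and acceptance runs use the full 261-cycle horizon for
deterministic results, 10,000 draws for headline PSA quantities, and
200–2,000 draws for structural PSA checks (reproducibility, CEAC
brute-force equivalence, seed-to-seed binomial variation), sizes at which
every Monte-Carlo comparison has comfortable statistical margin.

## Known limitations

- The engine's cycle-index time-scale convention reproduces the published
  totals but is not a literal reading of monthly Weibull parameters;
  both conventions are implemented, and arm-level totals differ
  materially between them.
- Costs after progression are a stylized mix (uncapped second-line
  therapy for a fixed proportion, BSC otherwise); no treatment switching,
  dose reductions, or relative dose intensity.
- Adverse events are a single lump of cost and disutility at model start
  rather than a time-resolved process.
- PSA acceptance probabilities reflect only the uncertainty the printed
  inputs encode (see above).
- No individual-level microsimulation, tunnel states, or time-varying
  hazard ratios within an arm.
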