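# Methods

## The score and its classification rule

The PreMiCC is a 0–6 point sum over five covariates available at the
diagnostic work-up of newly diagnosed Crohn's disease: age at first
diagnosis (≤40 y → 1), C-reactive protein (<2 mg/dL → 0, 2–4 → 1,
>4 → 2), the endoscopic grade of the worst bowel segment (>1 on a 0–4
scale → 1), perianal lesions (→ 1), and a composite complication flag
(stenosis, any fistula, extraintestinal manifestation, or fever >38 °C;
any one → 1). A total of ≤2 predicts a mild (nonprogressive) course.

Numerical conventions the published band edges leave open:

* The CRP middle band is the **closed** interval [2, 4] mg/dL, so the
  three bands partition [0, ∞): `crp = 2.0` and `crp = 4.0` both score
  1 point. CRP stays in mg/dL; published stratum medians of 1.4 and
  14.4 mg/dL would be more typical of mg/L, but we carry the stated
  units through unchanged.
* The endoscopic input is the already-reduced worst-segment grade;
  per-segment findings are not modeled.
* Missing covariates are rejected, not imputed: the study scored its
  whole cohort at baseline, so a scored record is always complete.

## Eligibility screen and flow

A screened patient enters the cohort if the diagnosis is at most
6 weeks old — implemented as an **inclusive** 42-day window (the source
material writes both "≤6 weeks" and "<6 weeks"; we fix one reading and
state it) — with at most 10 days of prior mesalazine or short-term oral
steroid (budesonide/prednisolone) exposure and none of: emergency case,
immediate inpatient need, clear surgical indication, complicating
infection. Exclusion reasons are reported in a fixed rule order
(diagnosis window, prior therapy, emergency, inpatient, surgery,
infection, screening error, consent), so the verdict is deterministic.
Multiple prior-therapy episodes are summed into one day count. The flow
arithmetic is `final = eligible − screening errors − withdrawals`, with
screening errors taking precedence over withdrawn consent so the
categories are disjoint.

## Event definitions

All timestamps are integer study-days from the baseline visit; months
are days / 30.4375 everywhere.

**Week-8 escalation.** Within days 0–56 a patient escalates if they
(1) received therapy other than mesalazine (a drug outside the
steroid/immunosuppressant/biologic classes, which rules 2–3 cover),
(2) were not steroid-free for the two weeks before the week-8 visit
(any budesonide or systemic-steroid exposure touching days 43–56),
(3) started an immunosuppressant or biologic, or (4) underwent
Crohn's-related surgery.

**Outcome failure** (the time-to-event endpoint) is the earliest of:
a steroid/budesonide course that goes beyond induction, the start of
any immunosuppressant or biologic, or an IBD-related hospitalization
or Crohn's-related surgery. The design permits induction steroids:
a course starting within the first 8 weeks and ending by day 42 does
**not** count as a failure; a course overlapping days 43–56 fails at
its first exposed day inside that window, and one starting after
day 56 fails at its start. This is one defensible reading of a
definition that does not say whether short induction courses count;
it is the one that makes the week-8 assessment and the failure
definition consistent. Week-8 escalation does not remove a patient
from the time-to-event analysis — their failure time is the
underlying failure day. Day-0 failures are clamped to 10⁻⁶ months so
the product-limit code never sees t = 0. When several criteria fire
on the same day the recorded failure kind follows a fixed order
(steroid, immunomodulator/biologic, surgery, hospitalization); only
the composite drives the analysis.

## Survival stack

The Kaplan–Meier estimator, Greenwood variance and the two-sample
log-rank test are implemented from first principles (they are the
analytic core being validated) and cross-checked in the test suite
against closed forms, hand-computed tables, the 1 − ECDF identity
under no censoring, and lifelines as an independent reference.

* Ties: events precede censorings at equal times, so a patient
  censored at an event time is still at risk there.
* Curves are tabulated at event times only; between them the estimate
  is a right-continuous step function.
* Confidence bands (default 95%) are Greenwood on the log(−log S)
  scale, which preserves [0, 1]; where S = 0 the band collapses to
  [0, 0] and where S = 1 to [1, 1].
* The log-rank statistic is the unweighted (O − E)²/V form with the
  hypergeometric variance at each distinct event time, referred to
  χ²(1) with no continuity correction; single-subject risk sets
  contribute no variance.

## Horizon diagnostics

The positive class is fixed as *mild*: a positive prediction is a
score ≤2 and a condition positive is a mild course (no failure by the
horizon with follow-up reaching the horizon), so sensitivity is
P(score ≤2 | mild course). Patients censored before the horizon
without an event are excluded from the 2×2 (complete-case horizon
analysis; the handling is not specified in the source and this is the
simplest defensible choice). Undefined metrics (empty denominator)
are reported as undefined, never silently zero.

The ROC sweeps "predict mild if total ≤ k" over k = −1..6; the AUC is
the pairwise-concordance (Mann–Whitney) statistic with ties counted
1/2, which equals the trapezoidal area under the sweep (property-
tested). The ROC outcome horizon is computed per configured horizon
(defaults 36 and 48 months) since a dichotomized-score AUC printed
alongside 48-month metrics cannot be reproduced uniquely; the package
reports the full-score ROC at each horizon and asserts nothing about
any single published AUC value.

Odds ratios order the groups (score >2, score ≤2), use the Woolf
log-interval, and apply the Haldane–Anscombe 0.5 correction when any
cell is zero. Baseline-table comparisons use chi-square without
continuity correction, switching to Fisher's exact test when any
expected cell is below 5 (the source lists both tests without a
switch rule; expected-cell-below-5 is the textbook convention), and
the two-sided Wilcoxon rank-sum test (normal approximation with tie
correction) for numeric variables. The endoscopic grade is compared
as the scored dichotomy (>1). No multiple-testing correction is
applied, mirroring per-variable significance flags at p < .05.

## Synthetic cohorts

Real patient-level data are not publicly available, so the pipeline
is exercised on simulated inception cohorts that reproduce the
statistical features the analysis relies on — and only those.

**Baseline covariates.** Two strata of 88 (score ≤2) and 113
(score >2) patients. Ages and CRP are log-normal around the stratum
medians (46 vs 29 years; 1.4 vs 14.4 mg/dL) with log-scale sigmas
(0.48/0.35 for age, 1.40/1.00 for CRP) chosen so the scored bands
roughly match the published band frequencies (e.g. ~39% vs ~82% aged
≤40; CRP <2 in ~60% vs ~3%). The endoscopic grade is categorical at
the published per-stratum category frequencies; the five flags are
independent Bernoulli at the published prevalences. Records are
rejection-resampled (bounded at 1000 tries) until the computed score
lands in the intended stratum, so scoring the generated baseline
recovers the stratum sizes exactly. Marginal-median fidelity, not
joint realism, is the goal: the pipeline needs score-stratum
consistency and plausible marginals, nothing more.

**Escalation hazards.** Piecewise-exponential, front-loaded: a high
segment over months 0–6 (rates 0.030 and 0.1417 per month for the
low/high stratum) and a tail rate solved so the cumulative escalation
probability at month 36 equals 24.2% (low) and 70.2% (high). More
than half of all events fall before month 6 under both defaults. A
separate single-arm scenario uses a constant hazard −ln(0.295)/36 ≈
0.03391 per month so the pooled escalation-free proportion at month
36 is 29.5%. The pooled and stratified published figures are
arithmetically incompatible as printed, so they are kept as distinct
calibration scenarios and never mixed. Event times are drawn by
inverse-CDF sampling of the piecewise-exponential survival function.

**Censoring and realization.** Censoring is the minimum of
administrative end-of-study (month 60 by default) and exponential
dropout (0.004/month — the source gives a mean follow-up of 38.4
months but no censoring distribution, so administrative censoring
plus small dropout is our assumption), snapped forward to the next
visit of the schedule 0, 3, 6, 9, 12, 18, 24, 30, 36, 48, 60 months,
because patients are observed only at scheduled visits. Planned
events before censoring are written into timelines as a biologic
episode starting on the event day (a configurable mix over
immunosuppressant/surgery/hospitalization realizations exists), on
top of background mesalazine from day 0, so the failure classifier
recovers every planned event day exactly (round-trip property-tested
across seeds). Planned events after censoring are dropped and the
patient censored.

One seeded `numpy` generator drives each run; identical config and
seed give byte-identical cohorts.

**What the generator does not emulate** — and hence what passing
tests do not show about real data: covariate correlations within a
stratum, fecal calprotectin dynamics, upper-GI involvement, center
effects, non-proportional or patient-specific hazards, and
informative censoring. The simulation demonstrates that the analysis
stack recovers known truth under its own assumptions, not that the
score performs as published in any external cohort.

## Validation model

`CohortValidation(dataset).fit()` composes scoring → event
derivation → survival → diagnostics deterministically and returns a
results object with stratum-wise KM curves, escalation proportions at
months 12/24/36 (reported as 1 − S(m), an identity that is
cross-checked as a property), the log-rank comparison, horizon
diagnostics at months 36 and 48 with Wilson 95% intervals, the ROC,
week-8 proportions, and the baseline-comparison table. Percentages
are rounded to one decimal only in the human-readable summary; JSON
output keeps full precision.

## Replicate sizes

Headline recovery checks average 500 replicate cohorts at the study's
stratum sizes (88/113/201 patients), which puts the Monte-Carlo
standard error of each recovered percentage well below the 0.5-point
tolerance asserted; the log-rank separation check uses 25 replicates
because the calibrated effect is large. Distributional checks on the
samplers use 5000–8000 draws against closed-form CDFs.

## Known limitations

* The horizon 2×2 is complete-case; with heavy early censoring the
  excluded fraction would bias accuracy estimates, which matters for
  real cohorts more than for the simulated ones.
* The eligibility screen models one combined prior-therapy exposure
  per patient; distinct sequential courses are summed in days.
* The induction-steroid reading above is a convention; cohorts whose
  induction courses routinely cross day 42 would shift early failure
  counts under a different reading.
* Published group-wise week-8 escalation proportions (19.6%/16.9%)
  are inconsistent with the printed overall 19.5%; the package treats
  the overall figure as the calibration truth for its week-8 recovery
  check and does not attempt to reconcile the triple.
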