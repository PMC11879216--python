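# premicc

Validation pipeline for the **PreMiCC** — the *prediction score for a
mild course of Crohn's disease* — aimed at biostatisticians and IBD
researchers who want to score inception cohorts, derive
treatment-escalation outcomes, and run the full time-to-event
validation on their own (or simulated) data.

## The problem

The course of newly diagnosed Crohn's disease (CD) is highly
variable: roughly 20–30% of patients have a mild, nonprogressive
course manageable with mesalazine alone, while others need early
immunosuppressants, biologics or surgery. Identifying the mild group
at diagnosis avoids overtreatment. The PreMiCC summarises five
covariates available at the diagnostic work-up into a 0–6 point
total:

| Parameter | Result | Points |
|---|---|---|
| Age at first diagnosis, y | ≤40 / >40 | 1 / 0 |
| CRP, mg/dL | <2 / 2–4 / >4 | 0 / 1 / 2 |
| Endoscopic score, worst segment (0–4) | ≤1 / >1 | 0 / 1 |
| Perianal lesions | no / yes | 0 / 1 |
| Complications (stenosis, fistula, EIM, fever >38 °C) | no / ≥1 | 0 / 1 |

A total of ≤2 predicts a mild course. The package validates the
score the way an inception-cohort study would:

* **events** — a week-8 escalation flag and a composite
  time-to-first-escalation endpoint (steroids beyond induction,
  immunosuppressants/biologics, IBD hospitalization or CD surgery)
  derived from therapy/event timelines;
* **survival** — Kaplan–Meier product-limit curves
  S(t) = ∏ₜᵢ≤ₜ (1 − dᵢ/nᵢ) with Greenwood variance and log(−log)
  bands, and the two-sample log-rank test, implemented from first
  principles and cross-checked against lifelines in the tests;
* **diagnostics** — horizon 2×2 classification (mild-predicted vs
  observed mild course), sensitivity/specificity/PPV/NPV with Wilson
  intervals, ROC/AUC over the integer score, odds ratios, and
  baseline-table group tests (chi-square / Fisher / Wilcoxon);
* **synthetic_data** — a seeded inception-cohort simulator with
  score-consistent stratified covariates, front-loaded
  piecewise-exponential escalation hazards calibrated to published
  stratum rates, and visit-grid censoring;
* **pipeline** — a statsmodels-style `CohortValidation` model whose
  `fit()` returns a `ValidationResults` object with a `summary()`
  table and JSON/CSV/plot rendering; plus a `premicc` CLI
  (`screen`, `score`, `simulate`, `validate`).

## Worked example

Score a single patient:

```python
>>> from premicc import BaselineRecord, compute_score
>>> rec = BaselineRecord(patient_id="P001", age_years=29, crp_mg_dl=14.4,
...                      endoscopic_score=3, perianal_lesions=False,
...                      stenosis=False, fistula=False, eim=False,
...                      fever_gt38=False)
>>> compute_score(rec)
PreMiCCResult(patient_id='P001', age_points=1, crp_points=2,
              endoscopy_points=1, perianal_points=0,
              complication_points=0, total=4,
              risk_class=<RiskClass.SEVERE_PREDICTED: 'severe_predicted'>)
```

Age 29 (≤40) scores 1, CRP 14.4 mg/dL (>4) scores 2, endoscopic grade
3 (>1) scores 1: total 4 > 2, so a severe course is predicted.

Simulate a default cohort (88 low-score + 113 high-score patients)
and run the full validation:

```python
from premicc import CohortValidation
from premicc.synthetic_data import CohortConfig, generate_cohort

results = CohortValidation(generate_cohort(CohortConfig(seed=1))).fit()
print(results.summary())
```

```
PreMiCC cohort validation
============================================================
Patients: 201  (score <=2: 88, score >2: 113)
Week-8 escalation: 16.9% overall
  score <=2: 4.5%
  score >2: 26.5%

Escalation proportions (1 - KM survival):
  month           12        24        36
  score<=2     19.7%     24.7%     27.2%
  score>2      62.9%     67.7%     71.7%

Log-rank: chi2 = 50.64, p = <.001

Diagnostics at month 36 (complete-case n = 189):
   sensitivity: 67.4%
   specificity: 77.7%
           PPV: 71.6%
           NPV: 74.1%
           AUC: 0.738
            OR: 7.20 (3.77-13.76)
...
```

The two strata — built to escalate at 24.2% vs 70.2% by month 36 —
are recovered by the survival stack (27.2% and 71.7% in this single
draw; the means across replicates converge to the calibrated rates)
and separated decisively by the log-rank test. The same analysis is
available from the shell:

```bash
premicc simulate --seed 1 --out cohort/
premicc validate --cohort cohort/ --out report/ --plots
```

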