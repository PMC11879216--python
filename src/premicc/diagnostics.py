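"""Horizon classification, diagnostic accuracy, ROC and group tests.

The score is validated against the observed disease course at a fixed
horizon (e.g. month 36 or 48).  Conventions:

* *Positive prediction* = mild-predicted (score <=2); *condition
  positive* = mild course, i.e. no treatment escalation by the
  horizon with follow-up reaching the horizon.  Sensitivity is then
  P(score <=2 | mild course).
* Patients censored before the horizon without an event carry no
  information about the horizon outcome and are excluded from the
  2x2 table (complete-case horizon analysis).
* The ROC sweeps "predict mild if total <= k" over k = -1..6 on the
  integer score; the AUC is the rank-statistic (concordance) form
  with ties counted 1/2.
* Odds ratios use the Woolf log-interval, with the Haldane-Anscombe
  0.5 correction when any cell is zero.
* Baseline-table group comparisons use chi-square (switching to
  Fisher's exact test when any expected cell is below 5) for
  categorical variables and the two-sided Wilcoxon rank-sum test
  (normal approximation with tie correction) for numeric ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .events import TimeToEventRecord
from .scoring import SCORE_MAX, SCORE_MIN, BaselineRecord, RiskClass

__all__ = [
    "ConfusionMatrix",
    "DiagnosticSummary",
    "RocResult",
    "OddsRatioResult",
    "ComparisonResult",
    "confusion_at_horizon",
    "diagnostic_metrics",
    "roc_auc",
    "odds_ratio",
    "compare_baseline",
    "wilson_interval",
    "NUMERIC_VARIABLES",
    "CATEGORICAL_VARIABLES",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 horizon table.

    Positive prediction = mild-predicted (score <=2); condition
    positive = mild course (no escalation by the horizon).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticSummary:
    """Accuracy metrics in [0, 1]; None marks an undefined metric
    (empty denominator), never a silent zero."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    horizon_months: Optional[float] = None


@dataclass(frozen=True)
class RocResult:
    """Threshold sweep points (fpr, tpr) from (0,0) to (1,1) and the
    concordance AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    corrected: bool  # Haldane-Anscombe 0.5 applied


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test_name: str  # chi_square | fisher_exact | wilcoxon_rank_sum
    statistic: float
    p_value: float
    significant: bool  # at p < .05


def confusion_at_horizon(
    tte: Sequence[TimeToEventRecord], horizon_months: float
) -> ConfusionMatrix:
    """Cross-classify score class against the observed course at a horizon.

    Condition positive (mild course) iff no event occurred by the
    horizon and follow-up reaches the horizon.  An event before the
    horizon makes the patient condition negative regardless of later
    follow-up; a patient censored before the horizon without an event
    is excluded from every cell.
    """
    if horizon_months <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon_months}")
    tp = fp = fn = tn = 0
    for r in tte:
        if r.risk_class is None:
            raise ValueError(f"record {r.patient_id} carries no risk class")
        if r.event and r.time_months <= horizon_months:
            mild_course = False
        elif r.time_months >= horizon_months:
            mild_course = True
        else:
            continue  # censored before horizon: uninformative
        predicted_mild = r.risk_class is RiskClass.MILD_PREDICTED
        if predicted_mild and mild_course:
            tp += 1
        elif predicted_mild and not mild_course:
            fp += 1
        elif not predicted_mild and mild_course:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def diagnostic_metrics(
    cm: ConfusionMatrix, horizon_months: Optional[float] = None
) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV from a 2x2 table."""
    return DiagnosticSummary(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        horizon_months=horizon_months,
    )


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be > 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = successes / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def roc_auc(scores: Sequence[tuple[int, bool]]) -> RocResult:
    """ROC over the integer score with a low-score-positive orientation.

    Parameters
    ----------
    scores : sequence of (total, mild)
        ``total`` is the 0-6 score; ``mild`` flags the observed mild
        course (the positive class).  Both classes must be present.

    The sweep predicts mild for total <= k, k = -1..6; the AUC is the
    pairwise-concordance (Mann-Whitney) statistic: a mild/non-mild
    pair is concordant when the mild patient scores lower, with ties
    counted 1/2.
    """
    totals = np.asarray([s for s, _ in scores], dtype=int)
    mild = np.asarray([m for _, m in scores], dtype=bool)
    if np.any((totals < SCORE_MIN) | (totals > SCORE_MAX)):
        raise ValueError("score totals must lie in 0..6")
    n_pos = int(mild.sum())
    n_neg = int((~mild).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both outcome classes")

    points = []
    for k in range(SCORE_MIN - 1, SCORE_MAX + 1):
        pred = totals <= k
        tpr = float(np.sum(pred & mild)) / n_pos
        fpr = float(np.sum(pred & ~mild)) / n_neg
        points.append((fpr, tpr))

    # concordance over score-value counts (low score indicates mild)
    pos_counts = np.bincount(totals[mild], minlength=SCORE_MAX + 1)
    neg_counts = np.bincount(totals[~mild], minlength=SCORE_MAX + 1)
    concordant = 0.0
    for s_pos in range(SCORE_MAX + 1):
        if pos_counts[s_pos] == 0:
            continue
        concordant += pos_counts[s_pos] * neg_counts[s_pos + 1 :].sum()
        concordant += 0.5 * pos_counts[s_pos] * neg_counts[s_pos]
    auc = concordant / (n_pos * n_neg)
    return RocResult(points=tuple(points), auc=float(auc))


def odds_ratio(
    escalated_a: int, total_a: int, escalated_b: int, total_b: int
) -> OddsRatioResult:
    """Odds ratio of escalation between two groups with Woolf 95% CI.

    Group ``a`` is conventionally the high-score (>2) stratum and
    ``b`` the low-score stratum.  Any zero cell triggers the
    Haldane-Anscombe 0.5 correction on all four cells.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("both groups must be nonempty")
    if not (0 <= escalated_a <= total_a and 0 <= escalated_b <= total_b):
        raise ValueError("escalated counts must lie within group totals")
    a = float(escalated_a)
    c = float(total_a - escalated_a)
    b = float(escalated_b)
    d = float(total_b - escalated_b)
    corrected = min(a, b, c, d) == 0.0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return OddsRatioResult(
        odds_ratio=or_,
        ci_lower=math.exp(math.log(or_) - z * se),
        ci_upper=math.exp(math.log(or_) + z * se),
        corrected=corrected,
    )


# Baseline-table variables; the endoscopic grade is compared as the
# scored dichotomy (grade >1), matching the table's primary row.
NUMERIC_VARIABLES = ("age_years", "crp_mg_dl")
CATEGORICAL_VARIABLES = (
    "endoscopic_score",
    "perianal_lesions",
    "stenosis",
    "fistula",
    "eim",
    "fever_gt38",
)


def _categorical_value(rec: BaselineRecord, variable: str) -> bool:
    if variable == "endoscopic_score":
        return rec.endoscopic_score > 1
    return bool(getattr(rec, variable))


def compare_baseline(
    group_a: Sequence[BaselineRecord],
    group_b: Sequence[BaselineRecord],
    variable: str,
) -> ComparisonResult:
    """Univariate comparison of one baseline variable between groups.

    Numeric variables use the two-sided Wilcoxon rank-sum test
    (normal approximation with tie correction); categorical ones use
    the chi-square test, switching to Fisher's exact test when any
    expected cell count is below 5.  Significance is flagged at
    p < .05.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if variable in NUMERIC_VARIABLES:
        x = [getattr(r, variable) for r in group_a]
        y = [getattr(r, variable) for r in group_b]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, p, name = float(res.statistic), float(res.pvalue), "wilcoxon_rank_sum"
    elif variable in CATEGORICAL_VARIABLES:
        a_true = sum(_categorical_value(r, variable) for r in group_a)
        b_true = sum(_categorical_value(r, variable) for r in group_b)
        table = np.array(
            [
                [a_true, len(group_a) - a_true],
                [b_true, len(group_b) - b_true],
            ],
            dtype=float,
        )
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if expected.min() < 5:
            odds, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
            stat, name = float(odds), "fisher_exact"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            stat, name = float(chi2), "chi_square"
        p = float(p)
    else:
        raise ValueError(f"unknown baseline variable {variable!r}")
    return ComparisonResult(
        variable=variable,
        test_name=name,
        statistic=stat,
        p_value=p,
        significant=p < 0.05,
    )
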