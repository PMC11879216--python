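"""PreMiCC scoring engine.

The PreMiCC ("prediction score for a mild course of Crohn's disease")
maps five covariates recorded at the diagnostic work-up of newly
diagnosed Crohn's disease to an integer total between 0 and 6:

==============================  =============  ======
Parameter                       Result         Points
==============================  =============  ======
Age at first diagnosis, years   <=40           1
                                >40            0
CRP, mg/dL                      <2             0
                                2-4            1
                                >4             2
Endoscopic score (worst         <=1            0
bowel segment, 0-4)             >1             1
Perianal lesions                no / yes       0 / 1
Complications (stenosis, any    no / yes(>=1)  0 / 1
fistula, extraintestinal
manifestation, fever >38 C)
==============================  =============  ======

A total of <=2 points classifies the patient as *mild-predicted*
(a nonprogressive course without treatment escalation is expected);
a total >2 as *severe-predicted*.

The CRP band boundaries are closed at 1 point ([2, 4] -> 1) so the
three bands partition [0, inf).  CRP stays in the units of the input
file (mg/dL); no conversion is applied.  Missing covariates are
rejected, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "RiskClass",
    "BaselineRecord",
    "PreMiCCResult",
    "score_age",
    "score_crp",
    "score_endoscopy",
    "score_flags",
    "compute_score",
    "classify_risk",
    "MILD_THRESHOLD",
    "SCORE_MIN",
    "SCORE_MAX",
]

#: Totals <= MILD_THRESHOLD are classified as mild-predicted.
MILD_THRESHOLD = 2
SCORE_MIN = 0
SCORE_MAX = 6

AGE_CUTOFF_YEARS = 40
CRP_LOW_MG_DL = 2.0
CRP_HIGH_MG_DL = 4.0
ENDOSCOPY_CUTOFF = 1


class RiskClass(str, Enum):
    """Predicted disease course from the score total."""

    MILD_PREDICTED = "mild_predicted"
    SEVERE_PREDICTED = "severe_predicted"


@dataclass(frozen=True)
class BaselineRecord:
    """One patient's diagnosis-time covariates.

    Parameters
    ----------
    patient_id : str
        Opaque identifier, unique within a cohort.
    age_years : int
        Age at first diagnosis, non-negative.
    crp_mg_dl : float
        C-reactive protein in mg/dL, non-negative.
    endoscopic_score : int
        Severity grade 0-4 of the bowel segment with the most severe
        lesions (0 no lesions ... 4 diffuse large ulcerations and/or
        stenosis).
    perianal_lesions, stenosis, fistula, eim, fever_gt38 : bool
        Perianal involvement and the four complication flags
        (stenosis, any fistula, extraintestinal manifestation,
        fever above 38 C).
    """

    patient_id: str
    age_years: int
    crp_mg_dl: float
    endoscopic_score: int
    perianal_lesions: bool
    stenosis: bool
    fistula: bool
    eim: bool
    fever_gt38: bool

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(
                f"age_years must be >= 0, got {self.age_years!r} "
                f"(patient {self.patient_id})"
            )
        if self.crp_mg_dl < 0:
            raise ValueError(
                f"crp_mg_dl must be >= 0, got {self.crp_mg_dl!r} "
                f"(patient {self.patient_id})"
            )
        if self.endoscopic_score not in (0, 1, 2, 3, 4):
            raise ValueError(
                f"endoscopic_score must be in 0..4, got "
                f"{self.endoscopic_score!r} (patient {self.patient_id})"
            )


@dataclass(frozen=True)
class PreMiCCResult:
    """Per-component points, total and risk classification."""

    patient_id: str
    age_points: int
    crp_points: int
    endoscopy_points: int
    perianal_points: int
    complication_points: int
    total: int
    risk_class: RiskClass

    def __post_init__(self) -> None:
        components = (
            self.age_points
            + self.crp_points
            + self.endoscopy_points
            + self.perianal_points
            + self.complication_points
        )
        if components != self.total:
            raise ValueError(
                f"total {self.total} does not equal component sum {components}"
            )
        if not SCORE_MIN <= self.total <= SCORE_MAX:
            raise ValueError(f"total must be in 0..6, got {self.total}")


def score_age(age_years: int) -> int:
    """1 point for age at first diagnosis <=40 years, else 0."""
    if age_years < 0:
        raise ValueError(f"age_years must be >= 0, got {age_years!r}")
    return 1 if age_years <= AGE_CUTOFF_YEARS else 0


def score_crp(crp_mg_dl: float) -> int:
    """CRP band points: <2 -> 0, [2, 4] -> 1, >4 -> 2 (mg/dL)."""
    if crp_mg_dl < 0:
        raise ValueError(f"crp_mg_dl must be >= 0, got {crp_mg_dl!r}")
    if crp_mg_dl < CRP_LOW_MG_DL:
        return 0
    if crp_mg_dl <= CRP_HIGH_MG_DL:
        return 1
    return 2


def score_endoscopy(endoscopic_score: int) -> int:
    """1 point for a worst-segment endoscopic grade >1, else 0."""
    if endoscopic_score not in (0, 1, 2, 3, 4):
        raise ValueError(
            f"endoscopic_score must be in 0..4, got {endoscopic_score!r}"
        )
    return 0 if endoscopic_score <= ENDOSCOPY_CUTOFF else 1


def score_flags(
    perianal: bool,
    stenosis: bool,
    fistula: bool,
    eim: bool,
    fever: bool,
) -> tuple[int, int]:
    """(perianal points, complication points).

    Perianal lesions score 1 point on their own; the complication
    point is awarded if at least one of stenosis, fistula,
    extraintestinal manifestation or fever >38 C is present.
    """
    perianal_points = 1 if perianal else 0
    complication_points = 1 if (stenosis or fistula or eim or fever) else 0
    return perianal_points, complication_points


def classify_risk(total: int) -> RiskClass:
    """Mild-predicted iff the total is <=2 points."""
    if not SCORE_MIN <= total <= SCORE_MAX:
        raise ValueError(f"total must be in 0..6, got {total!r}")
    return (
        RiskClass.MILD_PREDICTED
        if total <= MILD_THRESHOLD
        else RiskClass.SEVERE_PREDICTED
    )


def compute_score(rec: BaselineRecord) -> PreMiCCResult:
    """Score one baseline record: components, total, risk class."""
    age_points = score_age(rec.age_years)
    crp_points = score_crp(rec.crp_mg_dl)
    endoscopy_points = score_endoscopy(rec.endoscopic_score)
    perianal_points, complication_points = score_flags(
        rec.perianal_lesions, rec.stenosis, rec.fistula, rec.eim, rec.fever_gt38
    )
    total = (
        age_points
        + crp_points
        + endoscopy_points
        + perianal_points
        + complication_points
    )
    return PreMiCCResult(
        patient_id=rec.patient_id,
        age_points=age_points,
        crp_points=crp_points,
        endoscopy_points=endoscopy_points,
        perianal_points=perianal_points,
        complication_points=complication_points,
        total=total,
        risk_class=classify_risk(total),
    )
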