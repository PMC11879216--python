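"""Treatment-escalation events derived from longitudinal timelines.

Each patient's follow-up is an ordered list of therapy episodes
(drug class, start/stop study-day) and clinical events (Crohn's-related
surgery, IBD hospitalization), observed up to a last-contact day.
Two study outcomes are derived from it:

*Week-8 escalation* — at the week-8 visit a patient counts as escalated
if, within the first 56 days, they (1) received therapy other than
mesalazine, (2) were not steroid-free for the 2 weeks preceding the
visit, (3) received an immunosuppressant or biologic, or
(4) underwent Crohn's-related surgery.

*Outcome failure* (the event of the time-to-event analysis) — the
earliest of: a steroid or budesonide course beyond induction (a course
overlapping days 43-56, or starting after day 56; induction courses
that start within the first 8 weeks and end by day 42 do not count),
the start of any immunosuppressant or biologic, or an IBD-related
hospitalization or Crohn's-related surgery on any day.  Patients with
no failure are censored at last contact.

Times are converted to months with a fixed divisor of 30.4375
days/month.  A failure on day 0 is clamped to 1e-6 months so the
product-limit estimator never sees t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "DrugClass",
    "EventType",
    "FailureKind",
    "TherapyEpisode",
    "ClinicalEvent",
    "FollowUpTimeline",
    "TimeToEventRecord",
    "EventConfig",
    "DEFAULT_EVENT_CONFIG",
    "DAYS_PER_MONTH",
    "assess_week8_escalation",
    "derive_failure",
    "build_tte_dataset",
]

#: Fixed day-to-month conversion used in every analysis.
DAYS_PER_MONTH = 30.4375


class DrugClass(str, Enum):
    MESALAZINE = "mesalazine"
    BUDESONIDE = "budesonide"
    SYSTEMIC_STEROID = "systemic_steroid"
    IMMUNOSUPPRESSANT = "immunosuppressant"
    BIOLOGIC = "biologic"
    OTHER = "other"


#: Drug classes counted as steroid exposure for the steroid-free rule.
STEROID_CLASSES = frozenset({DrugClass.BUDESONIDE, DrugClass.SYSTEMIC_STEROID})
#: Drug classes whose initiation is an outcome failure on any day.
ADVANCED_CLASSES = frozenset({DrugClass.IMMUNOSUPPRESSANT, DrugClass.BIOLOGIC})


class EventType(str, Enum):
    CD_SURGERY = "cd_surgery"
    IBD_HOSPITALIZATION = "ibd_hospitalization"


class FailureKind(str, Enum):
    """Which escalation criterion produced the failure (deterministic
    tie-break order when several fire on the same day)."""

    STEROID = "steroid"
    IMMUNOMODULATOR_BIOLOGIC = "immunomodulator_biologic"
    SURGERY = "surgery"
    HOSPITALIZATION = "hospitalization"


_KIND_ORDER = {k: i for i, k in enumerate(FailureKind)}


@dataclass(frozen=True)
class TherapyEpisode:
    """One course of therapy; ``stop_day`` of None means ongoing."""

    drug_class: DrugClass
    start_day: int
    stop_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start_day < 0:
            raise ValueError(f"start_day must be >= 0, got {self.start_day}")
        if self.stop_day is not None and self.stop_day < self.start_day:
            raise ValueError(
                f"stop_day {self.stop_day} precedes start_day {self.start_day}"
            )


@dataclass(frozen=True)
class ClinicalEvent:
    kind: EventType
    day: int

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"event day must be >= 0, got {self.day}")


@dataclass(frozen=True)
class FollowUpTimeline:
    """Ordered therapy episodes + clinical events for one patient.

    All days are integer study-days relative to the baseline visit
    (day 0).  Open-ended episodes are truncated at last contact.
    ``visit_days`` records the attended visit grid (the maximum visit
    day defines ``last_contact_day``; when omitted it defaults to the
    single day ``last_contact_day``).
    """

    patient_id: str
    episodes: tuple[TherapyEpisode, ...]
    events: tuple[ClinicalEvent, ...]
    last_contact_day: int
    visit_days: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "episodes", tuple(self.episodes))
        object.__setattr__(self, "events", tuple(self.events))
        if not self.visit_days:
            object.__setattr__(self, "visit_days", (self.last_contact_day,))
        else:
            object.__setattr__(
                self, "visit_days", tuple(sorted(set(self.visit_days)))
            )
        if self.last_contact_day < 0:
            raise ValueError("last_contact_day must be >= 0")
        if max(self.visit_days) != self.last_contact_day:
            raise ValueError(
                f"patient {self.patient_id}: max visit day "
                f"{max(self.visit_days)} != last_contact_day "
                f"{self.last_contact_day}"
            )
        for ep in self.episodes:
            if ep.start_day > self.last_contact_day:
                raise ValueError(
                    f"patient {self.patient_id}: episode starts on day "
                    f"{ep.start_day} after last contact {self.last_contact_day}"
                )
        for ev in self.events:
            if ev.day > self.last_contact_day:
                raise ValueError(
                    f"patient {self.patient_id}: event on day {ev.day} "
                    f"after last contact {self.last_contact_day}"
                )


@dataclass(frozen=True)
class TimeToEventRecord:
    """(time in months, event indicator, risk stratum) for one patient."""

    patient_id: str
    time_months: float
    event: bool
    risk_class: Optional[object] = None  # scoring.RiskClass once joined
    failure_kind: Optional[FailureKind] = None

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(
                f"time_months must be > 0, got {self.time_months}"
            )


@dataclass(frozen=True)
class EventConfig:
    """Parameters of the escalation definitions.

    week8_day
        Day of the week-8 assessment visit (8 x 7 = 56).
    steroid_free_start
        First day of the required steroid-free window before the
        week-8 visit (56 - 14 + 1 = 43): steroid exposure on any day
        in [steroid_free_start, week8_day] violates the rule.
    days_per_month
        Fixed day-to-month divisor.
    min_time_months
        Clamp for day-0 failures so event times stay positive.
    """

    week8_day: int = 56
    steroid_free_start: int = 43
    days_per_month: float = DAYS_PER_MONTH
    min_time_months: float = 1e-6


DEFAULT_EVENT_CONFIG = EventConfig()


def _episode_stop(ep: TherapyEpisode, t: FollowUpTimeline) -> int:
    return t.last_contact_day if ep.stop_day is None else ep.stop_day


def assess_week8_escalation(
    t: FollowUpTimeline, cfg: EventConfig = DEFAULT_EVENT_CONFIG
) -> bool:
    """Week-8 escalation flag for one timeline.

    True iff within days 0..week8_day the patient received non-mesalazine
    therapy outside the steroid/advanced classes (rule 1), had steroid
    exposure overlapping the steroid-free window (rule 2), started an
    immunosuppressant or biologic (rule 3), or underwent Crohn's-related
    surgery (rule 4).  Episodes entirely after the week-8 visit are
    ignored.
    """
    w = cfg.week8_day
    for ep in t.episodes:
        if ep.start_day > w:
            continue
        if ep.drug_class is DrugClass.OTHER:
            return True
        if ep.drug_class in ADVANCED_CLASSES:
            return True
        if ep.drug_class in STEROID_CLASSES:
            if _episode_stop(ep, t) >= cfg.steroid_free_start:
                return True
    for ev in t.events:
        if ev.kind is EventType.CD_SURGERY and ev.day <= w:
            return True
    return False


def _failure_candidates(
    t: FollowUpTimeline, cfg: EventConfig
) -> list[tuple[int, int, FailureKind]]:
    """(day, kind-order, kind) for every escalation criterion that fires."""
    out: list[tuple[int, int, FailureKind]] = []
    for ep in t.episodes:
        if ep.drug_class in ADVANCED_CLASSES:
            out.append(
                (
                    ep.start_day,
                    _KIND_ORDER[FailureKind.IMMUNOMODULATOR_BIOLOGIC],
                    FailureKind.IMMUNOMODULATOR_BIOLOGIC,
                )
            )
        elif ep.drug_class in STEROID_CLASSES:
            if ep.start_day > cfg.week8_day:
                # steroid course initiated after the week-8 assessment
                out.append(
                    (ep.start_day, _KIND_ORDER[FailureKind.STEROID], FailureKind.STEROID)
                )
            elif _episode_stop(ep, t) >= cfg.steroid_free_start:
                # induction course running into the steroid-free window:
                # the failure day is the first exposed day inside it
                day = max(ep.start_day, cfg.steroid_free_start)
                out.append((day, _KIND_ORDER[FailureKind.STEROID], FailureKind.STEROID))
    for ev in t.events:
        kind = (
            FailureKind.SURGERY
            if ev.kind is EventType.CD_SURGERY
            else FailureKind.HOSPITALIZATION
        )
        out.append((ev.day, _KIND_ORDER[kind], kind))
    return out


def derive_failure(
    t: FollowUpTimeline, cfg: EventConfig = DEFAULT_EVENT_CONFIG
) -> TimeToEventRecord:
    """Time-to-first-failure record for one timeline.

    The failure time is the minimum over the per-criterion failure
    days; if no criterion fires the record is censored at last
    contact.  Times are reported in months (day / 30.4375), with
    day 0 clamped to ``cfg.min_time_months``.
    """
    candidates = _failure_candidates(t, cfg)
    if candidates:
        day, _, kind = min(candidates)
        if day > t.last_contact_day:
            raise ValueError(
                f"patient {t.patient_id}: failure day {day} after last "
                f"contact {t.last_contact_day}"
            )
        time = day / cfg.days_per_month
        return TimeToEventRecord(
            patient_id=t.patient_id,
            time_months=max(time, cfg.min_time_months),
            event=True,
            failure_kind=kind,
        )
    time = t.last_contact_day / cfg.days_per_month
    return TimeToEventRecord(
        patient_id=t.patient_id,
        time_months=max(time, cfg.min_time_months),
        event=False,
    )


def build_tte_dataset(
    cohort,
    scores: Sequence,
    cfg: EventConfig = DEFAULT_EVENT_CONFIG,
) -> list[TimeToEventRecord]:
    """Join per-patient failure records with the score risk class.

    Parameters
    ----------
    cohort : cohort_io.CohortDataset
    scores : sequence of scoring.PreMiCCResult
        Must cover every patient in the cohort.

    Returns records ordered by patient_id.
    """
    by_id = {s.patient_id: s for s in scores}
    out: list[TimeToEventRecord] = []
    for pid in sorted(cohort.timelines):
        if pid not in by_id:
            raise KeyError(f"no score for patient {pid}")
        rec = derive_failure(cohort.timelines[pid], cfg)
        out.append(
            TimeToEventRecord(
                patient_id=rec.patient_id,
                time_months=rec.time_months,
                event=rec.event,
                risk_class=by_id[pid].risk_class,
                failure_kind=rec.failure_kind,
            )
        )
    return out
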