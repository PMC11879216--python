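"""Cohort data model, CSV readers/writers and the eligibility screen.

An inception cohort is exchanged as four plain CSV tables
(UTF-8, comma-separated, header row):

``baseline.csv``
    patient_id, age_years, crp_mg_dl, endoscopic_score,
    perianal_lesions, stenosis, fistula, eim, fever_gt38 (flags 0/1)
``therapy.csv``
    patient_id, drug_class, start_day, stop_day (empty = ongoing)
``events.csv``
    patient_id, event_kind (cd_surgery | ibd_hospitalization), day
``visits.csv``
    patient_id, day — attended visits including last contact; the
    maximum day per patient is the censoring day.

All days are integer study-days relative to the baseline visit
(day 0); calendar dates are not modeled.

The eligibility screen reproduces the study-entry rules for an
inception cohort: a confirmed diagnosis at most 6 weeks (42 days,
inclusive) old, at most 10 days of prior mesalazine or short-term
oral steroid therapy, and none of the clinical exclusions (emergency
case, inpatient need, surgical indication, complicating infection).
Exclusion reasons are reported in a fixed rule order so the verdict
is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .events import (
    ClinicalEvent,
    DrugClass,
    EventType,
    FollowUpTimeline,
    TherapyEpisode,
)
from .scoring import BaselineRecord

__all__ = [
    "PriorTherapyKind",
    "ScreeningRecord",
    "ScreeningVerdict",
    "FlowCounts",
    "CohortDataset",
    "SchemaError",
    "screen_eligibility",
    "apply_flow",
    "read_cohort",
    "write_cohort",
    "read_screening",
    "DIAGNOSIS_WINDOW_DAYS",
    "MAX_PRIOR_THERAPY_DAYS",
]

#: "<6 weeks since diagnosis" implemented as an inclusive 42-day window.
DIAGNOSIS_WINDOW_DAYS = 42
#: Maximum days of prior mesalazine / short-term oral steroid therapy.
MAX_PRIOR_THERAPY_DAYS = 10


class SchemaError(ValueError):
    """A cohort table violates its schema (names file and row)."""


class PriorTherapyKind(str, Enum):
    NONE = "none"
    MESALAZINE = "mesalazine"
    BUDESONIDE = "budesonide"
    PREDNISOLONE = "prednisolone"
    OTHER = "other"


#: Prior-therapy kinds permitted for up to MAX_PRIOR_THERAPY_DAYS days.
_ALLOWED_PRIOR = frozenset(
    {
        PriorTherapyKind.MESALAZINE,
        PriorTherapyKind.BUDESONIDE,
        PriorTherapyKind.PREDNISOLONE,
    }
)


@dataclass(frozen=True)
class ScreeningRecord:
    """One screened patient's entry-criteria data."""

    patient_id: str
    days_since_diagnosis: int
    prior_therapy_kind: PriorTherapyKind
    prior_therapy_days: int
    emergency_case: bool = False
    inpatient_need: bool = False
    surgery_indication: bool = False
    complicating_infection: bool = False
    screening_error: bool = False
    consent_withdrawn: bool = False

    def __post_init__(self) -> None:
        if self.days_since_diagnosis < 0:
            raise ValueError(
                f"days_since_diagnosis must be >= 0, got "
                f"{self.days_since_diagnosis} (patient {self.patient_id})"
            )
        if self.prior_therapy_days < 0:
            raise ValueError(
                f"prior_therapy_days must be >= 0, got "
                f"{self.prior_therapy_days} (patient {self.patient_id})"
            )


@dataclass(frozen=True)
class ScreeningVerdict:
    eligible: bool
    reason: Optional[str] = None  # first failing rule's code, if excluded


# Fixed order of exclusion rules; the first failing rule is reported.
REASON_DIAGNOSIS_WINDOW = "diagnosis-window"
REASON_PRIOR_THERAPY = "prior-therapy"
REASON_EMERGENCY = "emergency"
REASON_INPATIENT = "inpatient"
REASON_SURGERY = "surgery"
REASON_INFECTION = "infection"
REASON_SCREENING_ERROR = "screening-error"
REASON_CONSENT = "consent"


def _clinical_exclusion(rec: ScreeningRecord) -> Optional[str]:
    """First failing clinical entry rule, or None if clinically eligible."""
    if rec.days_since_diagnosis > DIAGNOSIS_WINDOW_DAYS:
        return REASON_DIAGNOSIS_WINDOW
    if rec.prior_therapy_kind is not PriorTherapyKind.NONE:
        if (
            rec.prior_therapy_kind not in _ALLOWED_PRIOR
            or rec.prior_therapy_days > MAX_PRIOR_THERAPY_DAYS
        ):
            return REASON_PRIOR_THERAPY
    if rec.emergency_case:
        return REASON_EMERGENCY
    if rec.inpatient_need:
        return REASON_INPATIENT
    if rec.surgery_indication:
        return REASON_SURGERY
    if rec.complicating_infection:
        return REASON_INFECTION
    return None


def screen_eligibility(rec: ScreeningRecord) -> ScreeningVerdict:
    """Apply the study entry rules to one screening record.

    Rules are evaluated in a fixed order (diagnosis window, prior
    therapy, emergency, inpatient, surgery, infection, screening
    error, consent); the first failure determines the reason code.
    """
    reason = _clinical_exclusion(rec)
    if reason is not None:
        return ScreeningVerdict(False, reason)
    if rec.screening_error:
        return ScreeningVerdict(False, REASON_SCREENING_ERROR)
    if rec.consent_withdrawn:
        return ScreeningVerdict(False, REASON_CONSENT)
    return ScreeningVerdict(True)


@dataclass(frozen=True)
class FlowCounts:
    """Study-flow arithmetic: eligible minus errors minus withdrawals."""

    screened_eligible: int
    screening_errors: int
    withdrawals: int
    final_cohort: int


def apply_flow(records: Iterable[ScreeningRecord]) -> FlowCounts:
    """Count the cohort flow over a list of screening records.

    ``screened_eligible`` counts records passing every clinical entry
    rule; among those, ``screening_errors`` and ``withdrawals`` are
    removed (a screening error takes precedence over a withdrawn
    consent, so the categories are disjoint) and the final cohort is
    the remainder.
    """
    eligible = errors = withdrawals = 0
    for rec in records:
        if _clinical_exclusion(rec) is not None:
            continue
        eligible += 1
        if rec.screening_error:
            errors += 1
        elif rec.consent_withdrawn:
            withdrawals += 1
    return FlowCounts(
        screened_eligible=eligible,
        screening_errors=errors,
        withdrawals=withdrawals,
        final_cohort=eligible - errors - withdrawals,
    )


@dataclass
class CohortDataset:
    """Baseline covariates plus per-patient follow-up timelines."""

    baseline: list[BaselineRecord]
    timelines: dict[str, FollowUpTimeline] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.baseline]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate patient_id(s): {dup}")
        known = set(ids)
        for pid in self.timelines:
            if pid not in known:
                raise SchemaError(
                    f"timeline references unknown patient_id {pid!r}"
                )

    @property
    def patient_ids(self) -> list[str]:
        return sorted(r.patient_id for r in self.baseline)

    def __len__(self) -> int:
        return len(self.baseline)


# ---------------------------------------------------------------------------
# CSV I/O

BASELINE_COLUMNS = [
    "patient_id",
    "age_years",
    "crp_mg_dl",
    "endoscopic_score",
    "perianal_lesions",
    "stenosis",
    "fistula",
    "eim",
    "fever_gt38",
]
THERAPY_COLUMNS = ["patient_id", "drug_class", "start_day", "stop_day"]
EVENTS_COLUMNS = ["patient_id", "event_kind", "day"]
VISITS_COLUMNS = ["patient_id", "day"]

_FILES = {
    "baseline": "baseline.csv",
    "therapy": "therapy.csv",
    "events": "events.csv",
    "visits": "visits.csv",
}


def _check_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing column(s) {missing}")


def _row_err(fname: str, idx: int, exc: Exception) -> SchemaError:
    # pandas index is 0-based over data rows; +2 gives the file line
    return SchemaError(f"{fname}, row {idx + 2}: {exc}")


def read_cohort(directory: str | Path) -> CohortDataset:
    """Read the four cohort tables from ``directory``.

    Raises :class:`SchemaError` (naming file and row) on missing
    columns, invalid values, duplicate patient ids or timeline rows
    referencing unknown patients.
    """
    directory = Path(directory)
    frames = {}
    for key, fname in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise SchemaError(f"missing cohort file {fname} in {directory}")
        frames[key] = pd.read_csv(path, dtype={"patient_id": str})

    bdf = frames["baseline"]
    _check_columns(bdf, BASELINE_COLUMNS, "baseline.csv")
    baseline: list[BaselineRecord] = []
    for idx, row in bdf.iterrows():
        try:
            baseline.append(
                BaselineRecord(
                    patient_id=str(row["patient_id"]),
                    age_years=int(row["age_years"]),
                    crp_mg_dl=float(row["crp_mg_dl"]),
                    endoscopic_score=int(row["endoscopic_score"]),
                    perianal_lesions=bool(int(row["perianal_lesions"])),
                    stenosis=bool(int(row["stenosis"])),
                    fistula=bool(int(row["fistula"])),
                    eim=bool(int(row["eim"])),
                    fever_gt38=bool(int(row["fever_gt38"])),
                )
            )
        except ValueError as exc:
            raise _row_err("baseline.csv", idx, exc) from exc
    known = {r.patient_id for r in baseline}
    if len(known) != len(baseline):
        raise SchemaError("baseline.csv: duplicate patient_id")

    vdf = frames["visits"]
    _check_columns(vdf, VISITS_COLUMNS, "visits.csv")
    visit_days: dict[str, list[int]] = {}
    for idx, row in vdf.iterrows():
        pid = str(row["patient_id"])
        if pid not in known:
            raise _row_err(
                "visits.csv", idx, ValueError(f"unknown patient_id {pid!r}")
            )
        try:
            day = int(row["day"])
            if day < 0:
                raise ValueError(f"negative visit day {day}")
        except ValueError as exc:
            raise _row_err("visits.csv", idx, exc) from exc
        visit_days.setdefault(pid, []).append(day)

    tdf = frames["therapy"]
    _check_columns(tdf, THERAPY_COLUMNS, "therapy.csv")
    episodes: dict[str, list[TherapyEpisode]] = {}
    for idx, row in tdf.iterrows():
        pid = str(row["patient_id"])
        if pid not in known:
            raise _row_err(
                "therapy.csv", idx, ValueError(f"unknown patient_id {pid!r}")
            )
        try:
            stop = row["stop_day"]
            stop_day = None if pd.isna(stop) else int(stop)
            episodes.setdefault(pid, []).append(
                TherapyEpisode(
                    drug_class=DrugClass(str(row["drug_class"])),
                    start_day=int(row["start_day"]),
                    stop_day=stop_day,
                )
            )
        except ValueError as exc:
            raise _row_err("therapy.csv", idx, exc) from exc

    edf = frames["events"]
    _check_columns(edf, EVENTS_COLUMNS, "events.csv")
    events: dict[str, list[ClinicalEvent]] = {}
    for idx, row in edf.iterrows():
        pid = str(row["patient_id"])
        if pid not in known:
            raise _row_err(
                "events.csv", idx, ValueError(f"unknown patient_id {pid!r}")
            )
        try:
            events.setdefault(pid, []).append(
                ClinicalEvent(kind=EventType(str(row["event_kind"])), day=int(row["day"]))
            )
        except ValueError as exc:
            raise _row_err("events.csv", idx, exc) from exc

    timelines: dict[str, FollowUpTimeline] = {}
    for rec in baseline:
        pid = rec.patient_id
        if pid not in visit_days:
            raise SchemaError(
                f"visits.csv: no visit rows for patient {pid!r} "
                "(at least the baseline visit is required)"
            )
        days = sorted(set(visit_days[pid]))
        try:
            timelines[pid] = FollowUpTimeline(
                patient_id=pid,
                episodes=tuple(
                    sorted(
                        episodes.get(pid, ()),
                        key=lambda e: (e.start_day, e.drug_class.value),
                    )
                ),
                events=tuple(
                    sorted(events.get(pid, ()), key=lambda e: (e.day, e.kind.value))
                ),
                last_contact_day=days[-1],
                visit_days=tuple(days),
            )
        except ValueError as exc:
            raise SchemaError(f"timeline for patient {pid!r}: {exc}") from exc

    return CohortDataset(baseline=baseline, timelines=timelines)


def write_cohort(dataset: CohortDataset, directory: str | Path) -> dict[str, Path]:
    """Write the four cohort CSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    bl = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "age_years": r.age_years,
                "crp_mg_dl": r.crp_mg_dl,
                "endoscopic_score": r.endoscopic_score,
                "perianal_lesions": int(r.perianal_lesions),
                "stenosis": int(r.stenosis),
                "fistula": int(r.fistula),
                "eim": int(r.eim),
                "fever_gt38": int(r.fever_gt38),
            }
            for r in sorted(dataset.baseline, key=lambda r: r.patient_id)
        ],
        columns=BASELINE_COLUMNS,
    )

    trows, erows, vrows = [], [], []
    for pid in sorted(dataset.timelines):
        t = dataset.timelines[pid]
        for ep in t.episodes:
            trows.append(
                {
                    "patient_id": pid,
                    "drug_class": ep.drug_class.value,
                    "start_day": ep.start_day,
                    "stop_day": "" if ep.stop_day is None else ep.stop_day,
                }
            )
        for ev in t.events:
            erows.append(
                {"patient_id": pid, "event_kind": ev.kind.value, "day": ev.day}
            )
        for day in t.visit_days:
            vrows.append({"patient_id": pid, "day": day})

    paths = {
        "baseline": directory / _FILES["baseline"],
        "therapy": directory / _FILES["therapy"],
        "events": directory / _FILES["events"],
        "visits": directory / _FILES["visits"],
    }
    bl.to_csv(paths["baseline"], index=False)
    pd.DataFrame(trows, columns=THERAPY_COLUMNS).to_csv(paths["therapy"], index=False)
    pd.DataFrame(erows, columns=EVENTS_COLUMNS).to_csv(paths["events"], index=False)
    pd.DataFrame(vrows, columns=VISITS_COLUMNS).to_csv(paths["visits"], index=False)
    return paths


SCREENING_COLUMNS = [
    "patient_id",
    "days_since_diagnosis",
    "prior_therapy_kind",
    "prior_therapy_days",
    "emergency_case",
    "inpatient_need",
    "surgery_indication",
    "complicating_infection",
    "screening_error",
    "consent_withdrawn",
]


def read_screening(path: str | Path) -> list[ScreeningRecord]:
    """Read a screening table (one row per screened patient)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    _check_columns(df, SCREENING_COLUMNS, Path(path).name)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                ScreeningRecord(
                    patient_id=str(row["patient_id"]),
                    days_since_diagnosis=int(row["days_since_diagnosis"]),
                    prior_therapy_kind=PriorTherapyKind(
                        str(row["prior_therapy_kind"])
                    ),
                    prior_therapy_days=int(row["prior_therapy_days"]),
                    emergency_case=bool(int(row["emergency_case"])),
                    inpatient_need=bool(int(row["inpatient_need"])),
                    surgery_indication=bool(int(row["surgery_indication"])),
                    complicating_infection=bool(
                        int(row["complicating_infection"])
                    ),
                    screening_error=bool(int(row["screening_error"])),
                    consent_withdrawn=bool(int(row["consent_withdrawn"])),
                )
            )
        except ValueError as exc:
            raise _row_err(Path(path).name, idx, exc) from exc
    return out


def flow_to_json(counts: FlowCounts, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "screened_eligible": counts.screened_eligible,
                "screening_errors": counts.screening_errors,
                "withdrawals": counts.withdrawals,
                "final_cohort": counts.final_cohort,
            },
            indent=2,
        )
    )
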