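"""Domain types for longitudinal coded primary-care records.

A cohort is four linked tables: patients, dated coded events, imaging reports
with structured findings flags, and GP questionnaire responses. Clinical code
meaning is carried entirely by configurable code sets (Read-style code lists
grouped into named categories); the rule engine never inspects code strings
directly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

__all__ = [
    "CATEGORY_NAMES",
    "CodeSets",
    "CodedEvent",
    "Cohort",
    "ImagingReport",
    "Patient",
    "QuestionnaireResponse",
]

#: Recognised code-set category names. ``knee_oa`` and ``knee_pain`` drive the
#: case-identification algorithms; the ``exclusion_*`` and ``tkr`` sets drive
#: cohort exclusions; ``imaging`` marks procedure codes for knee x-ray/MRI.
CATEGORY_NAMES = (
    "knee_oa",
    "knee_pain",
    "imaging",
    "exclusion_ra",
    "exclusion_gout",
    "exclusion_pseudogout",
    "exclusion_psa",
    "tkr",
)

#: Rheumatic-disorder categories whose presence (two codes >= 7 days apart)
#: excludes a patient.
RHEUMATIC_EXCLUSION_CATEGORIES = (
    "exclusion_ra",
    "exclusion_gout",
    "exclusion_pseudogout",
    "exclusion_psa",
)

_DATE_MIN = dt.date(1900, 1, 1)
_DATE_MAX = dt.date(2100, 1, 1)


@dataclass(frozen=True)
class Patient:
    """One registered patient: demographics plus the registration interval."""

    patient_id: str
    sex: str  # "female" | "male"
    birth_year: int
    registration_start: dt.date
    registration_end: dt.date

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"{self.patient_id}: sex must be female/male, got {self.sex!r}")
        if self.registration_start > self.registration_end:
            raise ValueError(
                f"{self.patient_id}: registration_start after registration_end"
            )
        age_at_start = self.registration_start.year - self.birth_year
        if not 0 <= age_at_start <= 120:
            raise ValueError(
                f"{self.patient_id}: implausible age {age_at_start} at registration start"
            )

    def age_at(self, on: dt.date) -> int:
        """Age in whole years on a date (year arithmetic; records carry birth
        year only, not full date of birth)."""
        return on.year - self.birth_year


@dataclass(frozen=True)
class CodedEvent:
    """One dated clinical code for one patient — the atom the rule engine
    consumes."""

    patient_id: str
    code: str
    event_date: dt.date

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError(f"{self.patient_id}: empty code")
        if not _DATE_MIN <= self.event_date <= _DATE_MAX:
            raise ValueError(
                f"{self.patient_id}: event date {self.event_date} outside plausible range"
            )


@dataclass(frozen=True)
class ImagingReport:
    """Structured findings extracted from one knee x-ray or MRI report.

    ``source`` records provenance: ``coded`` reports come from procedure-code
    text comments, ``gp_transcribed`` findings were copied from GP notes or
    questionnaires. Both are interchangeable for gold-standard adjudication.
    """

    patient_id: str
    report_date: dt.date
    modality: str  # "xray" | "mri"
    definite_osteophytes: bool
    joint_space_narrowing: bool
    sclerosis: bool
    tibial_spiking: bool
    impression_oa: bool
    source: str = "coded"  # "coded" | "gp_transcribed"

    def __post_init__(self) -> None:
        if self.modality not in ("xray", "mri"):
            raise ValueError(f"{self.patient_id}: modality must be xray/mri, got {self.modality!r}")
        if self.source not in ("coded", "gp_transcribed"):
            raise ValueError(f"{self.patient_id}: bad report source {self.source!r}")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """GP questionnaire answers. ``pain_over_6_weeks`` is None when the GP
    left the question blank — missingness is explicit, never imputed."""

    patient_id: str
    pain_over_6_weeks: bool | None
    gp_cause_of_pain: str | None


class CodeSets:
    """Named, non-overlapping (within the diagnostic pair) clinical code sets.

    The knee_oa / knee_pain sets may not share codes: each diagnostic code
    must map to at most one category so that :meth:`categorize` is a function.
    """

    def __init__(self, sets: dict[str, list[str]]):
        unknown = set(sets) - set(CATEGORY_NAMES)
        if unknown:
            raise ValueError(f"unknown code-set categories: {sorted(unknown)}")
        self._sets: dict[str, tuple[str, ...]] = {
            name: tuple(dict.fromkeys(sets.get(name, ()))) for name in CATEGORY_NAMES
        }
        overlap = set(self._sets["knee_oa"]) & set(self._sets["knee_pain"])
        if overlap:
            raise ValueError(
                f"codes present in both knee_oa and knee_pain sets: {sorted(overlap)}"
            )
        self._index: dict[str, str] = {}
        for name, codes in self._sets.items():
            for code in codes:
                self._index.setdefault(code, name)

    def codes(self, category: str) -> tuple[str, ...]:
        return self._sets[category]

    def categorize(self, code: str) -> str | None:
        """Return the category containing ``code``, or None if unknown."""
        return self._index.get(code)

    def as_dict(self) -> dict[str, list[str]]:
        return {name: list(codes) for name, codes in self._sets.items()}

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CodeSets) and self._sets == other._sets

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        sizes = {k: len(v) for k, v in self._sets.items() if v}
        return f"CodeSets({sizes})"


def categorize_code(code: str, codesets: CodeSets) -> str | None:
    """Functional alias for :meth:`CodeSets.categorize`."""
    return codesets.categorize(code)


@dataclass
class Cohort:
    """A linked set of patients, events, imaging reports and questionnaires.

    Referential integrity (every event/imaging/questionnaire patient_id has a
    patient row) is enforced by :meth:`check`.
    """

    patients: dict[str, Patient] = field(default_factory=dict)
    events: list[CodedEvent] = field(default_factory=list)
    imaging: list[ImagingReport] = field(default_factory=list)
    questionnaires: dict[str, QuestionnaireResponse] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        known = set(self.patients)
        orphans = sorted(
            {e.patient_id for e in self.events if e.patient_id not in known}
            | {r.patient_id for r in self.imaging if r.patient_id not in known}
            | {q for q in self.questionnaires if q not in known}
        )
        if orphans:
            raise ValueError(f"records reference unknown patient ids: {orphans}")

    def __len__(self) -> int:
        return len(self.patients)

    def events_for(self, patient_id: str) -> list[CodedEvent]:
        return sorted(
            (e for e in self.events if e.patient_id == patient_id),
            key=lambda e: (e.event_date, e.code),
        )

    def imaging_for(self, patient_id: str) -> list[ImagingReport]:
        return sorted(
            (r for r in self.imaging if r.patient_id == patient_id),
            key=lambda r: r.report_date,
        )

    def events_by_patient(self) -> dict[str, list[CodedEvent]]:
        out: dict[str, list[CodedEvent]] = {pid: [] for pid in self.patients}
        for e in self.events:
            out[e.patient_id].append(e)
        for lst in out.values():
            lst.sort(key=lambda e: (e.event_date, e.code))
        return out

    def imaging_by_patient(self) -> dict[str, list[ImagingReport]]:
        out: dict[str, list[ImagingReport]] = {pid: [] for pid in self.patients}
        for r in self.imaging:
            out[r.patient_id].append(r)
        for lst in out.values():
            lst.sort(key=lambda r: r.report_date)
        return out

    def subset(self, patient_ids) -> "Cohort":
        """Restrict the cohort to the given patient ids (order-insensitive)."""
        keep = set(patient_ids)
        missing = keep - set(self.patients)
        if missing:
            raise KeyError(f"unknown patient ids: {sorted(missing)}")
        return Cohort(
            patients={pid: p for pid, p in self.patients.items() if pid in keep},
            events=[e for e in self.events if e.patient_id in keep],
            imaging=[r for r in self.imaging if r.patient_id in keep],
            questionnaires={
                pid: q for pid, q in self.questionnaires.items() if pid in keep
            },
        )
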