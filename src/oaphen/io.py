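"""Readers and writers for the delimited cohort tables and code-set config.

File layout (one directory, four CSV files):

* ``patients.csv``      — patient_id,sex,birth_year,registration_start,registration_end
* ``events.csv``        — patient_id,code,event_date
* ``imaging.csv``       — patient_id,report_date,modality,definite_osteophytes,
  joint_space_narrowing,sclerosis,tibial_spiking,impression_oa,source (booleans 0/1)
* ``questionnaire.csv`` — patient_id,pain_over_6_weeks,gp_cause_of_pain
  (empty pain field = answer missing)

Dates are ISO-8601 calendar dates. Parsing errors name the file, row and
column; referential-integrity violations list the offending patient ids.
"""

from __future__ import annotations

import csv
import datetime as dt
from importlib import resources
from pathlib import Path

import yaml

from oaphen.model import (
    CodeSets,
    CodedEvent,
    Cohort,
    ImagingReport,
    Patient,
    QuestionnaireResponse,
)

__all__ = [
    "default_codesets_path",
    "load_codesets",
    "load_cohort",
    "read_cohort",
    "save_cohort",
    "write_cohort",
]

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "registration_start", "registration_end"]
EVENT_COLUMNS = ["patient_id", "code", "event_date"]
IMAGING_COLUMNS = [
    "patient_id",
    "report_date",
    "modality",
    "definite_osteophytes",
    "joint_space_narrowing",
    "sclerosis",
    "tibial_spiking",
    "impression_oa",
    "source",
]
QUESTIONNAIRE_COLUMNS = ["patient_id", "pain_over_6_weeks", "gp_cause_of_pain"]


class CohortFormatError(ValueError):
    """A cohort table failed schema or referential-integrity checks."""


def _parse_date(value: str, path: Path, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise CohortFormatError(
            f"{path}: row {row}, column {column!r}: unparseable date {value!r}"
        ) from exc


def _parse_int(value: str, path: Path, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise CohortFormatError(
            f"{path}: row {row}, column {column!r}: expected integer, got {value!r}"
        ) from exc


def _parse_bool(value: str, path: Path, row: int, column: str) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise CohortFormatError(
        f"{path}: row {row}, column {column!r}: expected 0/1, got {value!r}"
    )


def _read_rows(path: Path, required: list[str], optional: tuple[str, ...] = ()):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise CohortFormatError(f"{path}: missing required columns {missing}")
        extra = [c for c in header if c not in required and c not in optional]
        if extra:
            raise CohortFormatError(f"{path}: unexpected columns {extra}")
        # DictReader row 1 is the header line, so data rows start at line 2.
        yield from ((i, row) for i, row in enumerate(reader, start=2))


def read_cohort(
    patients_path,
    events_path,
    imaging_path,
    questionnaire_path,
) -> Cohort:
    """Read the four cohort tables and return a validated :class:`Cohort`."""
    patients: dict[str, Patient] = {}
    p_path = Path(patients_path)
    for rownum, row in _read_rows(p_path, PATIENT_COLUMNS):
        pid = row["patient_id"]
        if pid in patients:
            raise CohortFormatError(f"{p_path}: row {rownum}: duplicate patient_id {pid!r}")
        patients[pid] = Patient(
            patient_id=pid,
            sex=row["sex"],
            birth_year=_parse_int(row["birth_year"], p_path, rownum, "birth_year"),
            registration_start=_parse_date(
                row["registration_start"], p_path, rownum, "registration_start"
            ),
            registration_end=_parse_date(
                row["registration_end"], p_path, rownum, "registration_end"
            ),
        )

    e_path = Path(events_path)
    events = [
        CodedEvent(
            patient_id=row["patient_id"],
            code=row["code"],
            event_date=_parse_date(row["event_date"], e_path, rownum, "event_date"),
        )
        for rownum, row in _read_rows(e_path, EVENT_COLUMNS)
    ]

    i_path = Path(imaging_path)
    imaging = []
    for rownum, row in _read_rows(i_path, IMAGING_COLUMNS[:-1], optional=("source",)):
        imaging.append(
            ImagingReport(
                patient_id=row["patient_id"],
                report_date=_parse_date(row["report_date"], i_path, rownum, "report_date"),
                modality=row["modality"],
                definite_osteophytes=_parse_bool(
                    row["definite_osteophytes"], i_path, rownum, "definite_osteophytes"
                ),
                joint_space_narrowing=_parse_bool(
                    row["joint_space_narrowing"], i_path, rownum, "joint_space_narrowing"
                ),
                sclerosis=_parse_bool(row["sclerosis"], i_path, rownum, "sclerosis"),
                tibial_spiking=_parse_bool(
                    row["tibial_spiking"], i_path, rownum, "tibial_spiking"
                ),
                impression_oa=_parse_bool(
                    row["impression_oa"], i_path, rownum, "impression_oa"
                ),
                source=row.get("source") or "coded",
            )
        )

    q_path = Path(questionnaire_path)
    questionnaires: dict[str, QuestionnaireResponse] = {}
    for rownum, row in _read_rows(q_path, QUESTIONNAIRE_COLUMNS):
        pid = row["patient_id"]
        if pid in questionnaires:
            raise CohortFormatError(f"{q_path}: row {rownum}: duplicate patient_id {pid!r}")
        pain_raw = row["pain_over_6_weeks"]
        pain = None if pain_raw == "" else _parse_bool(pain_raw, q_path, rownum, "pain_over_6_weeks")
        questionnaires[pid] = QuestionnaireResponse(
            patient_id=pid,
            pain_over_6_weeks=pain,
            gp_cause_of_pain=row["gp_cause_of_pain"] or None,
        )

    try:
        return Cohort(
            patients=patients,
            events=events,
            imaging=imaging,
            questionnaires=questionnaires,
        )
    except ValueError as exc:
        raise CohortFormatError(str(exc)) from exc


def load_cohort(directory) -> Cohort:
    """Read a cohort from a directory containing the four standard files."""
    d = Path(directory)
    return read_cohort(
        d / "patients.csv", d / "events.csv", d / "imaging.csv", d / "questionnaire.csv"
    )


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write the four cohort tables; output is deterministic (sorted rows)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    def b(x: bool) -> str:
        return "1" if x else "0"

    with (d / "patients.csv").open("w", newline="") as handle:
        w = csv.writer(handle)
        w.writerow(PATIENT_COLUMNS)
        for pid in sorted(cohort.patients):
            p = cohort.patients[pid]
            w.writerow(
                [p.patient_id, p.sex, p.birth_year, p.registration_start.isoformat(),
                 p.registration_end.isoformat()]
            )

    with (d / "events.csv").open("w", newline="") as handle:
        w = csv.writer(handle)
        w.writerow(EVENT_COLUMNS)
        for e in sorted(cohort.events, key=lambda e: (e.patient_id, e.event_date, e.code)):
            w.writerow([e.patient_id, e.code, e.event_date.isoformat()])

    with (d / "imaging.csv").open("w", newline="") as handle:
        w = csv.writer(handle)
        w.writerow(IMAGING_COLUMNS)
        for r in sorted(cohort.imaging, key=lambda r: (r.patient_id, r.report_date, r.source)):
            w.writerow(
                [r.patient_id, r.report_date.isoformat(), r.modality,
                 b(r.definite_osteophytes), b(r.joint_space_narrowing), b(r.sclerosis),
                 b(r.tibial_spiking), b(r.impression_oa), r.source]
            )

    with (d / "questionnaire.csv").open("w", newline="") as handle:
        w = csv.writer(handle)
        w.writerow(QUESTIONNAIRE_COLUMNS)
        for pid in sorted(cohort.questionnaires):
            q = cohort.questionnaires[pid]
            pain = "" if q.pain_over_6_weeks is None else b(q.pain_over_6_weeks)
            w.writerow([pid, pain, q.gp_cause_of_pain or ""])

    return d


# Back-compat style alias pair used by the CLI.
save_cohort = write_cohort


def default_codesets_path() -> Path:
    """Path of the packaged default code-set configuration."""
    return Path(resources.files("oaphen") / "data" / "codesets.yaml")


def load_codesets(path=None) -> CodeSets:
    """Load code sets from YAML (``category -> [codes]``); packaged defaults
    when no path is given. Overlap between knee_oa and knee_pain is rejected
    here, at load time."""
    p = Path(path) if path is not None else default_codesets_path()
    with p.open() as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{p}: expected a mapping of category -> code list")
    sets = {}
    for name, codes in raw.items():
        if codes is None:
            codes = []
        if not isinstance(codes, list) or not all(isinstance(c, str) for c in codes):
            raise ValueError(f"{p}: category {name!r} must map to a list of code strings")
        sets[name] = codes
    return CodeSets(sets)
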