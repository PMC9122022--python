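"""Eligibility, exclusion filtering and the temporal case-identification
rule engine.

Algorithms are declarative :class:`AlgorithmDefinition` records: code-count
rules over the knee_oa / knee_pain categories, an optional window in days, a
minimum separation between codes, and an optional imaging-proximity
requirement. Month-based windows are fixed day counts (6 months = 183 days,
12 months = 365 days, 2 years = 730 days), configurable per definition.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from oaphen.model import (
    RHEUMATIC_EXCLUSION_CATEGORIES,
    CodeSets,
    CodedEvent,
    Cohort,
    ImagingReport,
)

__all__ = [
    "AlgorithmDefinition",
    "CountRule",
    "EligibilityCriteria",
    "ExclusionOutcome",
    "apply_algorithm",
    "apply_exclusions",
    "default_algorithms",
    "default_algorithms_path",
    "evaluate_all",
    "index_date",
    "is_eligible",
    "load_algorithms",
    "meets_pair_rule",
]


@dataclass(frozen=True)
class CountRule:
    """``exactly k`` codes in the whole record, or ``at_least k`` codes
    subject to the definition's separation/window constraints."""

    kind: str  # "exactly" | "at_least"
    k: int

    def __post_init__(self) -> None:
        if self.kind not in ("exactly", "at_least"):
            raise ValueError(f"unknown count-rule kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("count-rule k must be >= 1")


@dataclass(frozen=True)
class AlgorithmDefinition:
    """One declarative case-identification rule.

    * single ``exactly k`` rule: exactly k codes of the category anywhere in
      the record (no temporal constraint);
    * single ``at_least k`` rule (k >= 2): k codes of the category with
      consecutive codes separated by >= ``min_separation_days`` and total
      span <= ``window_days`` (unbounded when the window is None);
    * both rules present: a cross-category pair — one knee_oa and one
      knee_pain code whose distance lies in
      [``min_separation_days``, ``window_days``];
    * ``require_imaging_within_days``: additionally an imaging code or coded
      report within that many days (either direction) of a qualifying
      diagnostic code date.
    """

    name: str
    oa_rule: CountRule | None = None
    pain_rule: CountRule | None = None
    window_days: int | None = None
    min_separation_days: int = 7
    require_imaging_within_days: int | None = None

    def __post_init__(self) -> None:
        if self.oa_rule is None and self.pain_rule is None:
            raise ValueError(f"{self.name}: at least one count rule is required")
        if self.window_days is not None and self.window_days <= self.min_separation_days:
            raise ValueError(
                f"{self.name}: window_days must exceed min_separation_days"
            )
        if self.min_separation_days < 0:
            raise ValueError(f"{self.name}: min_separation_days must be >= 0")
        if self.oa_rule is not None and self.pain_rule is not None:
            if not (
                self.oa_rule == CountRule("at_least", 1)
                and self.pain_rule == CountRule("at_least", 1)
            ):
                raise ValueError(
                    f"{self.name}: combination rules support at_least(1) + at_least(1) only"
                )

    def with_imaging_requirement(self, within_days: int = 730) -> "AlgorithmDefinition":
        return AlgorithmDefinition(
            name=f"{self.name}_img",
            oa_rule=self.oa_rule,
            pain_rule=self.pain_rule,
            window_days=self.window_days,
            min_separation_days=self.min_separation_days,
            require_imaging_within_days=within_days,
        )


@dataclass(frozen=True)
class EligibilityCriteria:
    """Cohort-selection window and patient-level eligibility bounds."""

    assessment_start: dt.date = dt.date(2000, 1, 1)
    assessment_end: dt.date = dt.date(2015, 5, 31)
    min_age: int = 40
    max_age: int = 90
    min_registration_days: int = 365

    def __post_init__(self) -> None:
        if self.assessment_start >= self.assessment_end:
            raise ValueError("assessment_start must precede assessment_end")
        if self.min_age >= self.max_age:
            raise ValueError("min_age must be below max_age")


#: Priority order for the single primary exclusion reason logged per patient.
EXCLUSION_PRIORITY = (
    "ra",
    "gout",
    "pseudogout",
    "psoriatic_arthritis",
    "tkr_before_index",
    "insufficient_data",
)

_CATEGORY_TO_REASON = {
    "exclusion_ra": "ra",
    "exclusion_gout": "gout",
    "exclusion_pseudogout": "pseudogout",
    "exclusion_psa": "psoriatic_arthritis",
}


@dataclass(frozen=True)
class ExclusionOutcome:
    patient_id: str
    excluded: bool
    reason: str  # one of EXCLUSION_PRIORITY or "none"

    def __post_init__(self) -> None:
        if self.excluded != (self.reason != "none"):
            raise ValueError("excluded flag inconsistent with reason")
        if self.reason != "none" and self.reason not in EXCLUSION_PRIORITY:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


def index_date(
    events: list[CodedEvent],
    codesets: CodeSets,
    criteria: EligibilityCriteria | None = None,
) -> dt.date | None:
    """Earliest knee_oa or knee_pain code date inside the assessment period,
    or None when the patient has no qualifying code there."""
    criteria = criteria or EligibilityCriteria()
    dates = [
        e.event_date
        for e in events
        if codesets.categorize(e.code) in ("knee_oa", "knee_pain")
        and criteria.assessment_start <= e.event_date <= criteria.assessment_end
    ]
    return min(dates) if dates else None


def is_eligible(patient, index: dt.date, criteria: EligibilityCriteria | None = None):
    """Age and registration eligibility at the index date.

    Returns ``(eligible, reasons)`` where ``reasons`` lists the failed
    checks (``age``, ``registration``).
    """
    criteria = criteria or EligibilityCriteria()
    if index is None:
        raise ValueError("is_eligible requires a non-null index date")
    reasons = []
    age = patient.age_at(index)
    if not criteria.min_age <= age <= criteria.max_age:
        reasons.append("age")
    registered_days = (
        min(index, patient.registration_end) - patient.registration_start
    ).days
    if (
        not patient.registration_start <= index <= patient.registration_end
        or registered_days < criteria.min_registration_days
    ):
        reasons.append("registration")
    return (not reasons, reasons)


def meets_pair_rule(
    dates: list[dt.date],
    min_separation_days: int,
    window_days: int | None,
) -> bool:
    """True iff some pair of dates is separated by at least
    ``min_separation_days`` and at most ``window_days`` (inclusive bounds;
    a None window removes the upper bound). ``dates`` must be sorted
    ascending; records are small, so the O(n^2) pair scan is fine.
    """
    for i, j in combinations(range(len(dates)), 2):
        gap = (dates[j] - dates[i]).days
        if gap < min_separation_days:
            continue
        if window_days is None or gap <= window_days:
            return True
    return False


def _meets_count_rule(
    dates: list[dt.date],
    rule: CountRule,
    min_separation_days: int,
    window_days: int | None,
) -> list[dt.date]:
    """Dates that participate in satisfying a single-category rule; empty
    list when the rule fails."""
    if rule.kind == "exactly":
        return sorted(dates) if len(dates) == rule.k else []
    if rule.k == 1:
        return sorted(dates)
    qualifying: set[dt.date] = set()
    for combo in combinations(sorted(dates), rule.k):
        gaps_ok = all(
            (combo[i + 1] - combo[i]).days >= min_separation_days
            for i in range(len(combo) - 1)
        )
        span_ok = window_days is None or (combo[-1] - combo[0]).days <= window_days
        if gaps_ok and span_ok:
            qualifying.update(combo)
    return sorted(qualifying)


def _qualifying_dates(
    events: list[CodedEvent], algorithm: AlgorithmDefinition, codesets: CodeSets
) -> list[dt.date]:
    """Diagnostic-code dates through which the definition is satisfied;
    empty when the patient does not satisfy it."""
    oa_dates = [e.event_date for e in events if codesets.categorize(e.code) == "knee_oa"]
    pain_dates = [
        e.event_date for e in events if codesets.categorize(e.code) == "knee_pain"
    ]

    if algorithm.oa_rule is not None and algorithm.pain_rule is not None:
        qualifying: set[dt.date] = set()
        for o in oa_dates:
            for p in pain_dates:
                gap = abs((o - p).days)
                if gap < algorithm.min_separation_days:
                    continue
                if algorithm.window_days is not None and gap > algorithm.window_days:
                    continue
                qualifying.update((o, p))
        return sorted(qualifying)

    if algorithm.oa_rule is not None:
        dates, rule = oa_dates, algorithm.oa_rule
    else:
        dates, rule = pain_dates, algorithm.pain_rule
    return _meets_count_rule(
        dates, rule, algorithm.min_separation_days, algorithm.window_days
    )


def _imaging_dates(
    events: list[CodedEvent],
    imaging: list[ImagingReport],
    codesets: CodeSets,
) -> list[dt.date]:
    # Documented imaging = imaging procedure codes plus coded reports;
    # GP-transcribed findings are chart-review data, not coded imaging.
    coded = [e.event_date for e in events if codesets.categorize(e.code) == "imaging"]
    coded += [r.report_date for r in imaging if r.source == "coded"]
    return sorted(set(coded))


def apply_algorithm(
    events: list[CodedEvent],
    imaging: list[ImagingReport],
    algorithm: AlgorithmDefinition,
    codesets: CodeSets,
) -> bool:
    """Decide one algorithm for one patient record."""
    qualifying = _qualifying_dates(events, algorithm, codesets)
    if not qualifying:
        return False
    if algorithm.require_imaging_within_days is None:
        return True
    bound = algorithm.require_imaging_within_days
    imaging_dates = _imaging_dates(events, imaging, codesets)
    return any(
        abs((img - d).days) <= bound for img in imaging_dates for d in qualifying
    )


def evaluate_all(
    cohort: Cohort,
    algorithms: list[AlgorithmDefinition],
    codesets: CodeSets,
) -> pd.DataFrame:
    """Boolean decision matrix, patients (rows, sorted by id) x algorithms."""
    names = [a.name for a in algorithms]
    if len(set(names)) != len(names):
        raise ValueError("duplicate algorithm names")
    events_by = cohort.events_by_patient()
    imaging_by = cohort.imaging_by_patient()
    pids = sorted(cohort.patients)
    data = {
        a.name: [
            apply_algorithm(events_by[pid], imaging_by[pid], a, codesets)
            for pid in pids
        ]
        for a in algorithms
    }
    return pd.DataFrame(data, index=pd.Index(pids, name="patient_id"), dtype=bool)


def apply_exclusions(
    cohort: Cohort,
    codesets: CodeSets,
    criteria: EligibilityCriteria | None = None,
    index_dates: dict[str, dt.date | None] | None = None,
    min_separation_days: int = 7,
):
    """Apply the exclusion rules and return ``(retained_cohort, outcomes)``.

    A patient is excluded when (a) any rheumatic-disorder exclusion category
    has two codes separated by at least ``min_separation_days`` anywhere in
    the record, (b) a total-knee-replacement code precedes the index date, or
    (c) the gold standard cannot be assessed (no questionnaire pain answer
    and no imaging report from any source). One primary reason is logged per
    patient, in fixed priority order, so the log is deterministic.
    """
    criteria = criteria or EligibilityCriteria()
    events_by = cohort.events_by_patient()
    imaging_by = cohort.imaging_by_patient()
    if index_dates is None:
        index_dates = {
            pid: index_date(events_by[pid], codesets, criteria)
            for pid in cohort.patients
        }

    outcomes: dict[str, ExclusionOutcome] = {}
    for pid in sorted(cohort.patients):
        events = events_by[pid]
        reasons: list[str] = []
        for category in RHEUMATIC_EXCLUSION_CATEGORIES:
            dates = sorted(
                e.event_date for e in events if codesets.categorize(e.code) == category
            )
            if meets_pair_rule(dates, min_separation_days, None):
                reasons.append(_CATEGORY_TO_REASON[category])
        index = index_dates.get(pid)
        if index is not None and any(
            e.event_date < index
            for e in events
            if codesets.categorize(e.code) == "tkr"
        ):
            reasons.append("tkr_before_index")
        questionnaire = cohort.questionnaires.get(pid)
        pain_answered = questionnaire is not None and questionnaire.pain_over_6_weeks is not None
        if not pain_answered and not imaging_by[pid]:
            reasons.append("insufficient_data")

        if reasons:
            primary = min(reasons, key=EXCLUSION_PRIORITY.index)
            outcomes[pid] = ExclusionOutcome(pid, True, primary)
        else:
            outcomes[pid] = ExclusionOutcome(pid, False, "none")

    retained = cohort.subset(pid for pid, o in outcomes.items() if not o.excluded)
    return retained, outcomes


def default_algorithms_path() -> Path:
    return Path(resources.files("oaphen") / "data" / "algorithms.yaml")


def _parse_rule(raw) -> CountRule | None:
    if raw is None:
        return None
    return CountRule(kind=raw["kind"], k=int(raw["k"]))


def load_algorithms(path=None) -> list[AlgorithmDefinition]:
    """Load algorithm definitions from YAML; packaged defaults otherwise."""
    p = Path(path) if path is not None else default_algorithms_path()
    with p.open() as handle:
        raw = yaml.safe_load(handle) or []
    if not isinstance(raw, list):
        raise ValueError(f"{p}: expected a list of algorithm definitions")
    algorithms = []
    for entry in raw:
        algorithms.append(
            AlgorithmDefinition(
                name=entry["name"],
                oa_rule=_parse_rule(entry.get("oa_rule")),
                pain_rule=_parse_rule(entry.get("pain_rule")),
                window_days=entry.get("window_days"),
                min_separation_days=int(entry.get("min_separation_days", 7)),
                require_imaging_within_days=entry.get("require_imaging_within_days"),
            )
        )
    return algorithms


def default_algorithms() -> list[AlgorithmDefinition]:
    """The eight primary definitions plus imaging-restricted variants."""
    return load_algorithms()
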