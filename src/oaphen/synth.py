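"""Synthetic cohort generation and deterministic validation fixtures.

Two kinds of data come out of this module:

* :func:`generate_cohort` — a stochastic cohort whose marginal statistics
  (age distribution, sex ratio, code and imaging frequencies, gold-standard
  prevalence) track the published sample characteristics; used for property
  and recovery tests.
* :func:`build_row_fixture` / :func:`build_exclusion_fixture` — fully
  deterministic cohorts engineered so that the complete pipeline (classify,
  adjudicate, validate) reproduces one published validation-table row, or
  the published exclusion attrition, exactly. No randomness is involved.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from oaphen.gold import report_text_to_flags
from oaphen.io import load_codesets
from oaphen.model import (
    CodeSets,
    CodedEvent,
    Cohort,
    ImagingReport,
    Patient,
    QuestionnaireResponse,
)
from oaphen.rules import AlgorithmDefinition, default_algorithms
from oaphen.stats import TwoByTwo

__all__ = [
    "GenerationError",
    "GeneratorParams",
    "IMAGING_SUBCOHORT_ROW_SPECS",
    "PRIMARY_ROW_SPECS",
    "RowFixtureSpec",
    "build_exclusion_fixture",
    "build_row_fixture",
    "generate_cohort",
]


class GenerationError(ValueError):
    """A generation constraint could not be satisfied."""


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the stochastic cohort generator.

    Conditional code probabilities are chosen so the implied marginals match
    the published sample: prevalence 0.67, P(>=1 OA code) ~ 0.60,
    P(>=1 pain code) ~ 0.78, P(imaging) 0.73, mean age 63.8 (SD 11.1),
    53% women.
    """

    n_patients: int
    prevalence: float = 0.67
    p_oa_code_given_case: float = 0.70
    p_oa_code_given_control: float = 0.40
    p_pain_code_given_case: float = 0.85
    p_pain_code_given_control: float = 0.64
    p_imaging: float = 0.73
    p_gp_report_when_uncoded: float = 1.0
    imaging_accuracy: float = 0.99
    imaging_false_positive_rate: float = 0.10
    p_pain_answer_given_case: float = 0.99
    p_pain_answer_given_control: float = 0.40
    p_questionnaire_missing: float = 0.0
    age_mean: float = 63.8
    age_sd: float = 11.1
    age_min: int = 40
    age_max: int = 90
    p_female: float = 0.53
    extra_codes_mean: float = 0.8
    exclusion_rates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        probs = {
            "prevalence": self.prevalence,
            "p_oa_code_given_case": self.p_oa_code_given_case,
            "p_oa_code_given_control": self.p_oa_code_given_control,
            "p_pain_code_given_case": self.p_pain_code_given_case,
            "p_pain_code_given_control": self.p_pain_code_given_control,
            "p_imaging": self.p_imaging,
            "p_gp_report_when_uncoded": self.p_gp_report_when_uncoded,
            "imaging_accuracy": self.imaging_accuracy,
            "imaging_false_positive_rate": self.imaging_false_positive_rate,
            "p_pain_answer_given_case": self.p_pain_answer_given_case,
            "p_pain_answer_given_control": self.p_pain_answer_given_control,
            "p_questionnaire_missing": self.p_questionnaire_missing,
            "p_female": self.p_female,
            **{f"exclusion_rates[{k}]": v for k, v in self.exclusion_rates.items()},
        }
        bad = {k: v for k, v in probs.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"probabilities outside [0, 1]: {bad}")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")


_ASSESSMENT_START = dt.date(2000, 1, 1)
_REGISTRATION_END = dt.date(2015, 12, 31)

_EXCLUSION_CATEGORY = {
    "ra": "exclusion_ra",
    "gout": "exclusion_gout",
    "pseudogout": "exclusion_pseudogout",
    "psoriatic_arthritis": "exclusion_psa",
    "tkr": "tkr",
}


def _report_text(qualifying: bool, rng: np.random.Generator) -> str:
    if qualifying:
        parts = ["definite osteophytes medial compartment"]
        if rng.random() < 0.5:
            parts.append("joint space narrowing")
        if rng.random() < 0.5:
            parts.append("impression: osteoarthritis")
        return "; ".join(parts)
    if rng.random() < 0.3:
        return "mild sclerosis; tibial spiking; no other abnormality"
    return "no abnormality detected"


def _week_offsets(rng: np.random.Generator, k: int, anchored: bool) -> list[int]:
    """k distinct week indices in 0..52 (so codes are >= 7 days apart);
    ``anchored`` forces week 0 to be included."""
    if k > 53:
        raise GenerationError("cannot place more than 53 codes 7 days apart in a year")
    if anchored:
        rest = rng.choice(np.arange(1, 53), size=k - 1, replace=False) if k > 1 else []
        weeks = [0, *map(int, rest)]
    else:
        weeks = list(map(int, rng.choice(np.arange(0, 53), size=k, replace=False)))
    return sorted(weeks)


def generate_cohort(params: GeneratorParams, codesets: CodeSets | None = None) -> Cohort:
    """Draw a reproducible synthetic cohort from a single seeded stream.

    Each patient carries a latent gold-standard status drawn at the
    prevalence; codes, imaging findings and questionnaire answers are then
    drawn conditionally on it. Diagnostic codes for one category are placed
    on distinct weeks within a year of the patient's anchor date, so
    same-category codes are always at least 7 days apart. Ages are drawn by
    inverse-CDF from a truncated normal so the stream is platform-stable.
    """
    codesets = codesets or load_codesets()
    rng = np.random.default_rng(params.seed)
    a = (params.age_min - params.age_mean) / params.age_sd
    b = (params.age_max - params.age_mean) / params.age_sd

    patients: dict[str, Patient] = {}
    events: list[CodedEvent] = []
    imaging: list[ImagingReport] = []
    questionnaires: dict[str, QuestionnaireResponse] = {}

    oa_codes = codesets.codes("knee_oa")
    pain_codes = codesets.codes("knee_pain")
    imaging_codes = codesets.codes("imaging")

    for i in range(params.n_patients):
        pid = f"S{i + 1:05d}"
        case = rng.random() < params.prevalence
        sex = "female" if rng.random() < params.p_female else "male"
        age = int(
            round(
                truncnorm.ppf(
                    rng.random(), a, b, loc=params.age_mean, scale=params.age_sd
                )
            )
        )
        age = min(max(age, params.age_min), params.age_max)

        anchor = _ASSESSMENT_START + dt.timedelta(days=int(rng.integers(540, 5230)))
        birth_year = anchor.year - age
        reg_start = anchor - dt.timedelta(days=int(rng.integers(400, 3650)))
        patients[pid] = Patient(pid, sex, birth_year, reg_start, _REGISTRATION_END)

        has_oa = rng.random() < (
            params.p_oa_code_given_case if case else params.p_oa_code_given_control
        )
        has_pain = rng.random() < (
            params.p_pain_code_given_case if case else params.p_pain_code_given_control
        )
        for present, codes, anchored in (
            (has_oa, oa_codes, True),
            (has_pain, pain_codes, not has_oa),
        ):
            if not present:
                continue
            k = 1 + min(int(rng.poisson(params.extra_codes_mean)), 5)
            for week in _week_offsets(rng, k, anchored):
                events.append(
                    CodedEvent(
                        pid,
                        str(rng.choice(codes)),
                        anchor + dt.timedelta(days=7 * week),
                    )
                )

        # Coded imaging at p_imaging; patients without imaging codes usually
        # still have findings transcribed from GP notes or questionnaires.
        has_coded_imaging = rng.random() < params.p_imaging
        has_gp_report = not has_coded_imaging and (
            rng.random() < params.p_gp_report_when_uncoded
        )
        if has_coded_imaging or has_gp_report:
            qualifies = rng.random() < (
                params.imaging_accuracy if case else params.imaging_false_positive_rate
            )
            report_date = anchor + dt.timedelta(days=int(rng.integers(0, 700)))
            flags = report_text_to_flags(_report_text(qualifies, rng))
            imaging.append(
                ImagingReport(
                    pid,
                    report_date,
                    modality="xray" if rng.random() < 0.85 else "mri",
                    source="coded" if has_coded_imaging else "gp_transcribed",
                    **flags,
                )
            )
            if has_coded_imaging:
                events.append(
                    CodedEvent(pid, str(rng.choice(imaging_codes)), report_date)
                )

        if rng.random() < params.p_questionnaire_missing:
            pain_answer, cause = None, None
        else:
            pain_answer = rng.random() < (
                params.p_pain_answer_given_case
                if case
                else params.p_pain_answer_given_control
            )
            cause = (
                "osteoarthritis"
                if case and rng.random() < 0.8
                else str(rng.choice(["injury", "other", "unknown"]))
            )
        questionnaires[pid] = QuestionnaireResponse(pid, pain_answer, cause)

        for condition, rate in params.exclusion_rates.items():
            if condition not in _EXCLUSION_CATEGORY:
                raise ValueError(f"unknown exclusion condition {condition!r}")
            if rng.random() >= rate:
                continue
            codes = codesets.codes(_EXCLUSION_CATEGORY[condition])
            if condition == "tkr":
                events.append(
                    CodedEvent(pid, codes[0], anchor - dt.timedelta(days=60))
                )
            else:
                for offset in (10, 24):
                    events.append(
                        CodedEvent(pid, codes[0], anchor + dt.timedelta(days=offset))
                    )

    return Cohort(
        patients=patients, events=events, imaging=imaging, questionnaires=questionnaires
    )


@dataclass(frozen=True)
class RowFixtureSpec:
    """Counts defining one validation-table row fixture."""

    algorithm: str
    n_total: int
    n_gold_positive: int
    n_satisfying: int
    n_tp: int

    def __post_init__(self) -> None:
        if self.n_satisfying > self.n_total:
            raise ValueError("n_satisfying exceeds n_total")
        if self.n_tp > min(self.n_satisfying, self.n_gold_positive):
            raise ValueError("n_tp exceeds n_satisfying or n_gold_positive")
        if self.n_gold_positive - self.n_tp > self.n_total - self.n_satisfying:
            raise ValueError("too many gold positives among non-satisfying patients")

    @property
    def expected(self) -> TwoByTwo:
        return TwoByTwo(
            tp=self.n_tp,
            fp=self.n_satisfying - self.n_tp,
            fn=self.n_gold_positive - self.n_tp,
            tn=self.n_total - self.n_satisfying - (self.n_gold_positive - self.n_tp),
        )


#: Published full-sample rows (n=85, 57 gold-positive): algorithm,
#: n_total, n_gold_positive, n_satisfying, n_tp. The gold-positive total is
#: the unique denominator consistent with every printed sensitivity.
PRIMARY_ROW_SPECS = [
    RowFixtureSpec("one_oa_code", 85, 57, 39, 25),
    RowFixtureSpec("one_pain_code", 85, 57, 44, 29),
    RowFixtureSpec("oa_ge2_6mo", 85, 57, 12, 11),
    RowFixtureSpec("pain_ge2_6mo", 85, 57, 22, 15),
    RowFixtureSpec("oa_and_pain_6mo", 85, 57, 32, 23),
    RowFixtureSpec("oa_ge2_12mo", 85, 57, 14, 12),
    RowFixtureSpec("pain_ge2_12mo", 85, 57, 30, 20),
    RowFixtureSpec("oa_and_pain_12mo", 85, 57, 32, 23),
]

#: Published imaging-restricted subcohort rows (n=62, 43 gold-positive).
IMAGING_SUBCOHORT_ROW_SPECS = [
    RowFixtureSpec("one_oa_code", 62, 43, 19, 14),
    RowFixtureSpec("one_pain_code", 62, 43, 37, 25),
    RowFixtureSpec("oa_ge2_6mo", 62, 43, 9, 8),
    RowFixtureSpec("pain_ge2_6mo", 62, 43, 21, 14),
    RowFixtureSpec("oa_and_pain_6mo", 62, 43, 24, 18),
    RowFixtureSpec("oa_ge2_12mo", 62, 43, 11, 9),
    RowFixtureSpec("pain_ge2_12mo", 62, 43, 28, 19),
    RowFixtureSpec("oa_and_pain_12mo", 62, 43, 24, 18),
]

_BASE_DATE = dt.date(2005, 3, 1)


def _positive_pattern(algorithm: AlgorithmDefinition) -> list[tuple[str, int]]:
    """(category, day-offset) events that satisfy the definition.

    Offsets keep qualifying pairs inside the 6-month window (day 30) or
    inside 12 months but outside 6 (day 300), so 6- and 12-month variants of
    the same rule are distinguishable.
    """
    window = algorithm.window_days
    second = 30 if window is None or window <= 183 else 300
    if algorithm.oa_rule is not None and algorithm.pain_rule is not None:
        return [("knee_oa", 0), ("knee_pain", second)]
    category = "knee_oa" if algorithm.oa_rule is not None else "knee_pain"
    rule = algorithm.oa_rule or algorithm.pain_rule
    if rule.kind == "exactly":
        return [(category, 30 * j) for j in range(rule.k)]
    if rule.k == 1:
        return [(category, 0)]
    step = second if rule.k == 2 else max(algorithm.min_separation_days, 30)
    return [(category, j * step) for j in range(rule.k)]


def _negative_pattern(algorithm: AlgorithmDefinition) -> list[tuple[str, int]]:
    """One code that yields an index date without satisfying the rule."""
    if algorithm.oa_rule is not None:
        return [("knee_pain", 0)] if algorithm.pain_rule is None else [("knee_oa", 0)]
    return [("knee_oa", 0)]


def build_row_fixture(
    spec: RowFixtureSpec,
    codesets: CodeSets | None = None,
    algorithm: AlgorithmDefinition | None = None,
    all_have_imaging: bool = False,
):
    """Deterministic cohort reproducing one validation-table row.

    Returns ``(cohort, expected)`` where ``expected`` is the implied 2x2
    table. The first ``n_satisfying`` patients carry events satisfying the
    named algorithm; the rest carry a single code of the complementary
    category. Gold status comes from questionnaire pain plus a qualifying or
    non-qualifying imaging report, so adjudication runs the real rules. With
    ``all_have_imaging`` every patient additionally gets an imaging
    procedure code and report at their index date (the imaging-restricted
    subcohort layout).
    """
    codesets = codesets or load_codesets()
    if algorithm is None:
        by_name = {a.name: a for a in default_algorithms()}
        algorithm = by_name[spec.algorithm]

    oa_code = codesets.codes("knee_oa")[0]
    pain_code = codesets.codes("knee_pain")[0]
    imaging_code = codesets.codes("imaging")[0]
    code_for = {"knee_oa": oa_code, "knee_pain": pain_code}

    positive_pattern = _positive_pattern(algorithm)
    negative_pattern = _negative_pattern(algorithm)
    n_fn = spec.n_gold_positive - spec.n_tp

    patients: dict[str, Patient] = {}
    events: list[CodedEvent] = []
    imaging: list[ImagingReport] = []
    questionnaires: dict[str, QuestionnaireResponse] = {}

    for i in range(spec.n_total):
        pid = f"F{i + 1:03d}"
        satisfies = i < spec.n_satisfying
        if satisfies:
            gold_positive = i < spec.n_tp
        else:
            gold_positive = i - spec.n_satisfying < n_fn
        patients[pid] = Patient(
            patient_id=pid,
            sex="female" if i % 2 == 0 else "male",
            birth_year=1945 + (i % 21),
            registration_start=dt.date(2000, 1, 1),
            registration_end=dt.date(2015, 12, 31),
        )
        pattern = positive_pattern if satisfies else negative_pattern
        for category, offset in pattern:
            events.append(
                CodedEvent(pid, code_for[category], _BASE_DATE + dt.timedelta(days=offset))
            )
        if all_have_imaging:
            events.append(CodedEvent(pid, imaging_code, _BASE_DATE))
        if gold_positive or all_have_imaging:
            imaging.append(
                ImagingReport(
                    patient_id=pid,
                    report_date=_BASE_DATE,
                    modality="xray",
                    definite_osteophytes=gold_positive,
                    joint_space_narrowing=False,
                    sclerosis=not gold_positive,
                    tibial_spiking=False,
                    impression_oa=False,
                )
            )
        questionnaires[pid] = QuestionnaireResponse(
            pid,
            pain_over_6_weeks=gold_positive,
            gp_cause_of_pain="osteoarthritis" if gold_positive else "other",
        )

    cohort = Cohort(
        patients=patients, events=events, imaging=imaging, questionnaires=questionnaires
    )
    return cohort, spec.expected


def build_exclusion_fixture(
    codesets: CodeSets | None = None,
    inject_exclusions: bool = True,
) -> Cohort:
    """93-patient cohort reproducing the published attrition: exclusion
    filtering retains 85, logging gout x4, RA x2, TKR-before-index x1 and
    insufficient-data x1. With ``inject_exclusions=False`` the exclusion
    material is left out and all 93 are retained.

    Among the 85 retained, 57 are gold-standard positive (the published 67%
    prevalence).
    """
    codesets = codesets or load_codesets()
    oa_code = codesets.codes("knee_oa")[0]
    gout_code = codesets.codes("exclusion_gout")[0]
    ra_code = codesets.codes("exclusion_ra")[0]
    tkr_code = codesets.codes("tkr")[0]

    patients: dict[str, Patient] = {}
    events: list[CodedEvent] = []
    imaging: list[ImagingReport] = []
    questionnaires: dict[str, QuestionnaireResponse] = {}

    def add_patient(i: int, gold_positive: bool, answered: bool = True) -> str:
        pid = f"E{i:03d}"
        patients[pid] = Patient(
            patient_id=pid,
            sex="female" if i % 2 == 0 else "male",
            birth_year=1944 + (i % 23),
            registration_start=dt.date(2000, 1, 1),
            registration_end=dt.date(2015, 12, 31),
        )
        events.append(CodedEvent(pid, oa_code, _BASE_DATE))
        if gold_positive:
            imaging.append(
                ImagingReport(
                    patient_id=pid,
                    report_date=_BASE_DATE,
                    modality="xray",
                    definite_osteophytes=True,
                    joint_space_narrowing=True,
                    sclerosis=False,
                    tibial_spiking=False,
                    impression_oa=True,
                )
            )
        questionnaires[pid] = QuestionnaireResponse(
            pid,
            pain_over_6_weeks=gold_positive if answered else None,
            gp_cause_of_pain="osteoarthritis" if gold_positive else None,
        )
        return pid

    # 85 analysable patients, 57 of them gold-positive.
    for i in range(1, 86):
        add_patient(i, gold_positive=i <= 57)

    if not inject_exclusions:
        for i in range(86, 94):
            add_patient(i, gold_positive=False)
        return Cohort(
            patients=patients,
            events=events,
            imaging=imaging,
            questionnaires=questionnaires,
        )

    # Four gout and two RA exclusions: two codes 14 days apart.
    for i, code in [(86, gout_code), (87, gout_code), (88, gout_code), (89, gout_code),
                    (90, ra_code), (91, ra_code)]:
        pid = add_patient(i, gold_positive=True)
        events.append(CodedEvent(pid, code, dt.date(2004, 3, 1)))
        events.append(CodedEvent(pid, code, dt.date(2004, 3, 15)))
    # One knee replacement before the first diagnostic code.
    pid = add_patient(92, gold_positive=True)
    events.append(CodedEvent(pid, tkr_code, dt.date(2004, 6, 1)))
    # One patient with no pain answer and no imaging: gold standard not
    # assessable.
    add_patient(93, gold_positive=False, answered=False)

    return Cohort(
        patients=patients, events=events, imaging=imaging, questionnaires=questionnaires
    )
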