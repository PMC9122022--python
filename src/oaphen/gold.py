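"""Rule-based gold-standard adjudication of knee OA status.

A patient is gold-standard positive when the questionnaire confirms knee pain
lasting more than six weeks AND at least one x-ray/MRI report shows findings
consistent with OA: definite osteophytes, joint space narrowing, or a
radiologist impression of OA / degenerative arthritis. Sclerosis or tibial
spiking alone do not qualify. Coded and GP-transcribed reports are
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

from oaphen.model import Cohort, ImagingReport, QuestionnaireResponse

__all__ = [
    "GoldStandardStatus",
    "adjudicate",
    "adjudicate_cohort",
    "imaging_consistent_with_oa",
    "report_text_to_flags",
]


@dataclass(frozen=True)
class GoldStandardStatus:
    patient_id: str
    status: str  # "oa_positive" | "oa_negative" | "indeterminate"
    basis: str  # "coded_imaging" | "gp_transcribed_imaging" | "none"

    def __post_init__(self) -> None:
        if self.status not in ("oa_positive", "oa_negative", "indeterminate"):
            raise ValueError(f"bad status {self.status!r}")
        if self.basis not in ("coded_imaging", "gp_transcribed_imaging", "none"):
            raise ValueError(f"bad basis {self.basis!r}")
        if self.status == "indeterminate" and self.basis != "none":
            raise ValueError("indeterminate status cannot cite an imaging basis")


def imaging_consistent_with_oa(report: ImagingReport) -> bool:
    """Definite osteophytes OR joint space narrowing OR radiologist
    impression of OA. Sclerosis/tibial spiking alone are insufficient."""
    return (
        report.definite_osteophytes
        or report.joint_space_narrowing
        or report.impression_oa
    )


def adjudicate(
    reports: list[ImagingReport],
    questionnaire: QuestionnaireResponse | None,
) -> GoldStandardStatus:
    """Adjudicate one patient from their imaging reports and questionnaire.

    * positive — pain >6 weeks confirmed and any report (coded or
      GP-transcribed) consistent with OA;
    * negative — pain answer present but false, or pain confirmed with no
      qualifying report;
    * indeterminate — pain answer missing (status cannot be established;
      with no reports at all this is the "insufficient data" exclusion).

    No date constraint is applied to reports: imaging recency belongs to
    cohort selection and the imaging-restricted algorithms, not to the
    reference standard.
    """
    pid = (
        questionnaire.patient_id
        if questionnaire is not None
        else (reports[0].patient_id if reports else "")
    )
    pain = questionnaire.pain_over_6_weeks if questionnaire is not None else None
    if pain is None:
        return GoldStandardStatus(pid, "indeterminate", "none")

    qualifying = [r for r in reports if imaging_consistent_with_oa(r)]
    if pain and qualifying:
        # Coded reports take precedence in the logged basis.
        basis = (
            "coded_imaging"
            if any(r.source == "coded" for r in qualifying)
            else "gp_transcribed_imaging"
        )
        return GoldStandardStatus(pid, "oa_positive", basis)
    return GoldStandardStatus(pid, "oa_negative", "none")


def adjudicate_cohort(cohort: Cohort) -> dict[str, GoldStandardStatus]:
    """Adjudicate every patient in the cohort."""
    imaging_by = cohort.imaging_by_patient()
    return {
        pid: adjudicate(imaging_by[pid], cohort.questionnaires.get(pid))
        for pid in sorted(cohort.patients)
    }


# Keyword mapper for the synthetic generator's canned report strings. Not an
# NLP component: it only needs to invert the generator's own phrasing.
_KEYWORDS = {
    "definite_osteophytes": ("definite osteophyte",),
    "joint_space_narrowing": ("joint space narrowing",),
    "sclerosis": ("sclerosis",),
    "tibial_spiking": ("tibial spiking",),
    "impression_oa": ("impression: osteoarthritis", "degenerative arthritis"),
}


def report_text_to_flags(text: str) -> dict[str, bool]:
    """Map a short report string to findings flags by keyword matching."""
    lowered = text.lower()
    return {
        flag: any(kw in lowered for kw in kws) for flag, kws in _KEYWORDS.items()
    }
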