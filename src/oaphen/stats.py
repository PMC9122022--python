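"""Contingency construction, PPV/sensitivity with 95% Wald intervals, and
cohort summary statistics.

Intervals are the normal-approximation (Wald) form ``p +/- z*sqrt(p(1-p)/n)``
with z = 1.959964, clipped to [0, 100] and rounded half-away-from-zero to one
decimal — the convention that reproduces published SAS ``senspec`` output.
Undefined quantities (empty denominators) are reported as missing, never as
0 or 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from oaphen.gold import GoldStandardStatus
from oaphen.model import CodeSets, Cohort
from oaphen.rules import EligibilityCriteria, index_date

__all__ = [
    "CohortSummary",
    "TwoByTwo",
    "ValidationResult",
    "Z_95",
    "contingency",
    "ppv",
    "round_half_up",
    "sensitivity",
    "summarize_cohort",
    "validate",
    "wald_ci",
]

#: Two-sided 97.5% normal quantile as used by SAS for 95% intervals.
Z_95 = 1.959964


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (0.05 -> 0.1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwo:
    """Algorithm decision vs gold-standard status contingency counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_test_positive(self) -> int:
        return self.tp + self.fp

    @property
    def n_gold_positive(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class ValidationResult:
    """PPV and sensitivity (with 95% CIs) for one algorithm — one report row."""

    algorithm: str
    n_satisfying: int
    n_tp: int
    ppv_pct: float | None
    ppv_ci: tuple[float, float] | None
    sens_pct: float | None
    sens_ci: tuple[float, float] | None

    def __post_init__(self) -> None:
        for point, ci in ((self.ppv_pct, self.ppv_ci), (self.sens_pct, self.sens_ci)):
            if (point is None) != (ci is None):
                raise ValueError("point estimate and CI must be missing together")
            if point is not None and not (0 <= ci[0] <= point <= ci[1] <= 100):
                raise ValueError(f"CI {ci} does not bracket {point} within [0, 100]")


def contingency(
    decisions: "pd.Series | dict[str, bool]",
    gold: "dict[str, GoldStandardStatus] | dict[str, str]",
) -> TwoByTwo:
    """Cross-tabulate one algorithm's decisions against gold status.

    The two patient sets must coincide and contain no indeterminate
    adjudications (those are excluded upstream).
    """
    dec = dict(decisions.items()) if isinstance(decisions, pd.Series) else dict(decisions)
    statuses = {
        pid: (s.status if isinstance(s, GoldStandardStatus) else s)
        for pid, s in gold.items()
    }
    if set(dec) != set(statuses):
        only_dec = sorted(set(dec) - set(statuses))
        only_gold = sorted(set(statuses) - set(dec))
        raise ValueError(
            f"patient sets differ: only in decisions {only_dec}, only in gold {only_gold}"
        )
    indeterminate = sorted(p for p, s in statuses.items() if s == "indeterminate")
    if indeterminate:
        raise ValueError(
            f"indeterminate gold status for {indeterminate}; exclude these first"
        )
    tp = fp = fn = tn = 0
    for pid, decided in dec.items():
        positive = statuses[pid] == "oa_positive"
        if decided and positive:
            tp += 1
        elif decided:
            fp += 1
        elif positive:
            fn += 1
        else:
            tn += 1
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def ppv(t: TwoByTwo) -> float | None:
    """Positive predictive value, percent, one decimal; None when no patient
    tests positive."""
    if t.n_test_positive == 0:
        return None
    return round_half_up(100.0 * t.tp / t.n_test_positive)


def sensitivity(t: TwoByTwo) -> float | None:
    """Sensitivity, percent, one decimal; None when no patient is
    gold-positive."""
    if t.n_gold_positive == 0:
        return None
    return round_half_up(100.0 * t.tp / t.n_gold_positive)


def wald_ci(k: int, n: int, z: float = Z_95) -> tuple[float, float] | None:
    """95% Wald interval for k/n, percent scale, clipped to [0, 100]."""
    if n == 0:
        return None
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    lo = max(0.0, 100.0 * (p - half))
    hi = min(100.0, 100.0 * (p + half))
    return (round_half_up(lo), round_half_up(hi))


def _result_for(name: str, t: TwoByTwo) -> ValidationResult:
    return ValidationResult(
        algorithm=name,
        n_satisfying=t.n_test_positive,
        n_tp=t.tp,
        ppv_pct=ppv(t),
        ppv_ci=wald_ci(t.tp, t.n_test_positive),
        sens_pct=sensitivity(t),
        sens_ci=wald_ci(t.tp, t.n_gold_positive),
    )


def validate(
    decisions: pd.DataFrame,
    gold: dict[str, GoldStandardStatus],
) -> list[ValidationResult]:
    """One :class:`ValidationResult` per decision-matrix column.

    Indeterminate patients must already have been excluded; their presence
    raises (via :func:`contingency`).
    """
    return [
        _result_for(name, contingency(decisions[name], gold))
        for name in decisions.columns
    ]


def results_frame(results: list[ValidationResult]) -> pd.DataFrame:
    """Tabular form of validation results (the validation.csv schema)."""
    return pd.DataFrame(
        [
            {
                "algorithm": r.algorithm,
                "n_satisfying": r.n_satisfying,
                "n_tp": r.n_tp,
                "ppv": r.ppv_pct,
                "ppv_lo": r.ppv_ci[0] if r.ppv_ci else None,
                "ppv_hi": r.ppv_ci[1] if r.ppv_ci else None,
                "sens": r.sens_pct,
                "sens_lo": r.sens_ci[0] if r.sens_ci else None,
                "sens_hi": r.sens_ci[1] if r.sens_ci else None,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class CohortSummary:
    """Sample-characteristics summary (ages at index; percentages rounded to
    whole points)."""

    n: int
    mean_age: float
    sd_age: float
    pct_women: int
    pct_with_oa_code: int
    pct_with_pain_code: int
    pct_with_imaging: int
    pct_gold_positive: int


def summarize_cohort(
    cohort: Cohort,
    gold: dict[str, GoldStandardStatus],
    codesets: CodeSets,
    criteria: EligibilityCriteria | None = None,
) -> CohortSummary:
    """Deterministic sample summary for a filtered analysis cohort.

    Age is taken at the patient's index date; patients with no index code
    are aged at the assessment-period midpoint.
    """
    if not cohort.patients:
        raise ValueError("cannot summarize an empty cohort")
    criteria = criteria or EligibilityCriteria()
    midpoint = criteria.assessment_start + (
        criteria.assessment_end - criteria.assessment_start
    ) / 2
    events_by = cohort.events_by_patient()
    imaging_by = cohort.imaging_by_patient()

    ages = []
    n_women = n_oa = n_pain = n_imaging = n_gold = 0
    n = len(cohort.patients)
    for pid, patient in cohort.patients.items():
        idx = index_date(events_by[pid], codesets, criteria) or midpoint
        ages.append(patient.age_at(idx))
        n_women += patient.sex == "female"
        categories = {codesets.categorize(e.code) for e in events_by[pid]}
        n_oa += "knee_oa" in categories
        n_pain += "knee_pain" in categories
        # "% with imaging" counts coded imaging (procedure codes or coded
        # reports), not findings transcribed from GP notes.
        n_imaging += (
            any(r.source == "coded" for r in imaging_by[pid]) or "imaging" in categories
        )
        status = gold.get(pid)
        n_gold += status is not None and status.status == "oa_positive"

    mean_age = sum(ages) / n
    sd_age = math.sqrt(sum((a - mean_age) ** 2 for a in ages) / (n - 1)) if n > 1 else 0.0

    def pct(k: int) -> int:
        return int(round_half_up(100.0 * k / n, 0))

    return CohortSummary(
        n=n,
        mean_age=round_half_up(mean_age),
        sd_age=round_half_up(sd_age),
        pct_women=pct(n_women),
        pct_with_oa_code=pct(n_oa),
        pct_with_pain_code=pct(n_pain),
        pct_with_imaging=pct(n_imaging),
        pct_gold_positive=pct(n_gold),
    )
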