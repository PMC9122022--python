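"""End-to-end orchestration: cohort in, validation tables out.

Stages: read/generate -> index dates & eligibility -> exclusions ->
classification -> gold-standard adjudication -> PPV/sensitivity validation ->
summary. Every stage writes a plain-CSV artifact and the run log records the
attrition count at each step.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from oaphen import reference
from oaphen.gold import adjudicate_cohort
from oaphen.io import load_codesets, load_cohort, write_cohort
from oaphen.model import Cohort
from oaphen.rules import (
    EligibilityCriteria,
    apply_exclusions,
    evaluate_all,
    index_date,
    is_eligible,
    load_algorithms,
)
from oaphen.stats import results_frame, summarize_cohort, validate
from oaphen.synth import (
    IMAGING_SUBCOHORT_ROW_SPECS,
    PRIMARY_ROW_SPECS,
    GeneratorParams,
    build_exclusion_fixture,
    build_row_fixture,
    generate_cohort,
)

__all__ = [
    "RunConfig",
    "read_decisions",
    "read_gold",
    "reproduce_paper",
    "run_pipeline",
    "write_decisions",
    "write_gold",
]

log = logging.getLogger("oaphen")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one cohort source plus config paths."""

    out_dir: str
    cohort_dir: str | None = None
    generator: GeneratorParams | None = None
    codesets_path: str | None = None
    algorithms_path: str | None = None
    seed: int | None = None
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if (self.cohort_dir is None) == (self.generator is None):
            raise ValueError(
                "exactly one of cohort_dir / generator must be configured"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        generator = raw.get("generator")
        if generator is not None:
            generator = GeneratorParams(**generator)
        return cls(
            out_dir=raw["out_dir"],
            cohort_dir=raw.get("cohort_dir"),
            generator=generator,
            codesets_path=raw.get("codesets"),
            algorithms_path=raw.get("algorithms"),
            seed=raw.get("seed"),
            verbosity=raw.get("verbosity", "info"),
        )


def write_decisions(decisions: pd.DataFrame, path) -> None:
    decisions.astype(int).to_csv(path, index_label="patient_id")


def read_decisions(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="patient_id", dtype={"patient_id": str})
    return frame.astype(bool)


def write_gold(gold, path) -> None:
    rows = [
        {"patient_id": pid, "status": s.status, "basis": s.basis}
        for pid, s in sorted(gold.items())
    ]
    pd.DataFrame(rows, columns=["patient_id", "status", "basis"]).to_csv(
        path, index=False
    )


def read_gold(path) -> dict[str, str]:
    frame = pd.read_csv(path, dtype=str)
    return dict(zip(frame["patient_id"], frame["status"]))


def _summary_text(summary) -> str:
    lines = [
        f"n analysed                      {summary.n}",
        f"mean age in years (SD)          {summary.mean_age} ({summary.sd_age})",
        f"% women                         {summary.pct_women}",
        f"% with one or more OA codes     {summary.pct_with_oa_code}",
        f"% with one or more pain codes   {summary.pct_with_pain_code}",
        f"% with imaging                  {summary.pct_with_imaging}",
        f"% OA by gold standard           {summary.pct_gold_positive}",
    ]
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write artifacts to ``config.out_dir``.

    Returns the output directory. Attrition counts (input -> eligible ->
    post-exclusion -> adjudicable) are logged and written to ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        return _run_stages(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path) -> Path:
    codesets = load_codesets(config.codesets_path)
    algorithms = load_algorithms(config.algorithms_path)
    criteria = EligibilityCriteria()

    if config.generator is not None:
        params = config.generator
        if config.seed is not None:
            params = replace(params, seed=config.seed)
        if params.n_patients == 0:
            raise ValueError("generator configured with n_patients=0: nothing to run")
        cohort = generate_cohort(params, codesets)
        write_cohort(cohort, out / "cohort")
        log.info("stage generate: %d patients (seed %s)", len(cohort), params.seed)
    else:
        cohort = load_cohort(config.cohort_dir)
        log.info("stage read: %d patients from %s", len(cohort), config.cohort_dir)
    if not cohort.patients:
        raise ValueError("input cohort is empty")

    events_by = cohort.events_by_patient()
    indices = {
        pid: index_date(events_by[pid], codesets, criteria) for pid in cohort.patients
    }
    eligible_ids = [
        pid
        for pid, idx in indices.items()
        if idx is not None and is_eligible(cohort.patients[pid], idx, criteria)[0]
    ]
    log.info("stage eligibility: %d of %d eligible", len(eligible_ids), len(cohort))
    cohort = cohort.subset(eligible_ids)

    cohort, outcomes = apply_exclusions(cohort, codesets, criteria, indices)
    reasons = sorted(
        (o.reason for o in outcomes.values() if o.excluded),
    )
    log.info(
        "stage exclusions: %d retained, %d excluded (%s)",
        len(cohort),
        sum(o.excluded for o in outcomes.values()),
        ", ".join(reasons) or "none",
    )
    pd.DataFrame(
        [
            {"patient_id": o.patient_id, "excluded": int(o.excluded), "reason": o.reason}
            for o in sorted(outcomes.values(), key=lambda o: o.patient_id)
        ]
    ).to_csv(out / "exclusions.csv", index=False)

    gold = adjudicate_cohort(cohort)
    indeterminate = [p for p, s in gold.items() if s.status == "indeterminate"]
    if indeterminate:
        log.warning(
            "stage adjudicate: dropping %d indeterminate patients: %s",
            len(indeterminate),
            indeterminate,
        )
        cohort = cohort.subset(set(cohort.patients) - set(indeterminate))
        gold = {p: s for p, s in gold.items() if p not in indeterminate}
    write_gold(gold, out / "gold_standard.csv")
    log.info(
        "stage adjudicate: %d analysable, %d gold-positive",
        len(gold),
        sum(s.status == "oa_positive" for s in gold.values()),
    )

    decisions = evaluate_all(cohort, algorithms, codesets)
    write_decisions(decisions, out / "decisions.csv")
    log.info("stage classify: %d algorithms evaluated", decisions.shape[1])

    results = validate(decisions, gold)
    results_frame(results).to_csv(out / "validation.csv", index=False)

    summary = summarize_cohort(cohort, gold, codesets, criteria)
    (out / "summary.txt").write_text(_summary_text(summary))
    log.info("stage validate: wrote validation.csv and summary.txt")
    return out


def _run_fixture_row(spec, codesets, algorithms_by_name, imaging_subcohort: bool):
    name = spec.algorithm + ("_img" if imaging_subcohort else "")
    algorithm = algorithms_by_name[name]
    cohort, _ = build_row_fixture(
        spec,
        codesets,
        algorithm=algorithm,
        all_have_imaging=imaging_subcohort,
    )
    gold = adjudicate_cohort(cohort)
    decisions = evaluate_all(cohort, [algorithm], codesets)
    (result,) = validate(decisions, gold)
    return result


def reproduce_paper(stream=None) -> bool:
    """Recompute every published table cell from the shipped fixtures through
    the full pipeline and compare. Prints one pass/fail line per cell group;
    returns True when everything matches.
    """

    def emit(line: str) -> None:
        if stream is not None:
            stream.write(line + "\n")

    codesets = load_codesets()
    algorithms_by_name = {a.name: a for a in load_algorithms()}
    ok = True

    for label, specs, expected, imaging_subcohort in (
        ("full sample", PRIMARY_ROW_SPECS, reference.PRIMARY_RESULTS, False),
        (
            "imaging subcohort",
            IMAGING_SUBCOHORT_ROW_SPECS,
            reference.IMAGING_SUBCOHORT_RESULTS,
            True,
        ),
    ):
        for spec in specs:
            result = _run_fixture_row(spec, codesets, algorithms_by_name, imaging_subcohort)
            n_sat, n_tp, ppv, ppv_ci, sens, sens_ci = expected[spec.algorithm]
            computed = (
                result.n_satisfying,
                result.n_tp,
                result.ppv_pct,
                result.ppv_ci,
                result.sens_pct,
                result.sens_ci,
            )
            target = (n_sat, n_tp, ppv, ppv_ci, sens, sens_ci)
            good = computed == target
            ok &= good
            emit(
                f"[{'PASS' if good else 'FAIL'}] {label}: {spec.algorithm} "
                f"computed={computed} expected={target}"
            )

    fixture = build_exclusion_fixture(codesets)
    retained, outcomes = apply_exclusions(fixture, codesets)
    histogram: dict[str, int] = {}
    for o in outcomes.values():
        if o.excluded:
            histogram[o.reason] = histogram.get(o.reason, 0) + 1
    att = reference.ATTRITION
    good = len(fixture) == att["returned"] and len(retained) == att["retained"] and (
        histogram == att["reasons"]
    )
    ok &= good
    emit(
        f"[{'PASS' if good else 'FAIL'}] attrition: {len(fixture)} -> {len(retained)} "
        f"retained, reasons {histogram}"
    )

    params = GeneratorParams(n_patients=2000, seed=3)
    cohort = generate_cohort(params, codesets)
    gold = adjudicate_cohort(cohort)
    summary = summarize_cohort(cohort, gold, codesets)
    tolerances = {
        "mean_age": 0.5,
        "sd_age": 1.0,
        "pct_women": 3,
        "pct_with_oa_code": 3,
        "pct_with_pain_code": 3,
        "pct_with_imaging": 3,
        "pct_gold_positive": 3,
    }
    for field_name, target in reference.SAMPLE_CHARACTERISTICS.items():
        value = getattr(summary, field_name)
        good = abs(value - target) <= tolerances[field_name]
        ok &= good
        emit(
            f"[{'PASS' if good else 'FAIL'}] sample characteristics (n=2000 generated): "
            f"{field_name} computed={value} expected~{target} "
            f"(tolerance {tolerances[field_name]})"
        )
    return ok
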