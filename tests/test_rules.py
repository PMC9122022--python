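import datetime as dt
import random
from itertools import combinations

import pytest

from oaphen.model import CodedEvent, Cohort, ImagingReport, Patient, QuestionnaireResponse
from oaphen.rules import (
    AlgorithmDefinition,
    CountRule,
    EligibilityCriteria,
    apply_algorithm,
    apply_exclusions,
    default_algorithms,
    evaluate_all,
    index_date,
    is_eligible,
    load_algorithms,
    meets_pair_rule,
)
from oaphen.synth import GeneratorParams, generate_cohort

from conftest import BASE, events_at


def make_patient(pid="P1", birth_year=1950, start=dt.date(2000, 1, 1), end=dt.date(2015, 12, 31)):
    return Patient(pid, "female", birth_year, start, end)


class TestIndexDate:
    def test_pre_period_code_ignored(self, codesets, oa_code, pain_code):
        events = [
            CodedEvent("P1", oa_code, dt.date(1999, 6, 1)),
            CodedEvent("P1", pain_code, dt.date(2003, 2, 10)),
        ]
        assert index_date(events, codesets) == dt.date(2003, 2, 10)

    def test_no_diagnostic_codes(self, codesets):
        events = [CodedEvent("P1", "ZZZZZ", dt.date(2003, 2, 10))]
        assert index_date(events, codesets) is None

    def test_same_day_tie(self, codesets, oa_code, pain_code):
        events = [
            CodedEvent("P1", pain_code, dt.date(2001, 1, 5)),
            CodedEvent("P1", oa_code, dt.date(2001, 1, 5)),
        ]
        assert index_date(events, codesets) == dt.date(2001, 1, 5)

    def test_post_period_code_ignored(self, codesets, oa_code):
        events = [CodedEvent("P1", oa_code, dt.date(2016, 1, 1))]
        assert index_date(events, codesets) is None


class TestEligibility:
    def test_eligible(self):
        patient = make_patient(birth_year=1960, start=dt.date(2000, 1, 1), end=dt.date(2010, 1, 1))
        ok, reasons = is_eligible(patient, dt.date(2005, 1, 1))
        assert ok and reasons == []

    def test_too_young(self):
        patient = make_patient(birth_year=1980)
        ok, reasons = is_eligible(patient, dt.date(2005, 1, 1))
        assert not ok and reasons == ["age"]

    def test_short_registration(self):
        patient = make_patient(start=dt.date(2004, 10, 1))
        ok, reasons = is_eligible(patient, dt.date(2005, 1, 1))
        assert not ok and reasons == ["registration"]

    def test_age_boundaries_inclusive(self):
        for birth_year in (1965, 1915):  # ages 40 and 90 at 2005
            ok, _ = is_eligible(make_patient(birth_year=birth_year), dt.date(2005, 1, 1))
            assert ok

    def test_requires_index(self):
        with pytest.raises(ValueError):
            is_eligible(make_patient(), None)


class TestMeetsPairRule:
    def test_boundary_inclusive(self):
        dates = [BASE, BASE + dt.timedelta(days=7)]
        assert meets_pair_rule(dates, 7, 183)

    def test_below_separation(self):
        dates = [BASE, BASE + dt.timedelta(days=5)]
        assert not meets_pair_rule(dates, 7, 183)

    def test_window_boundary_inclusive(self):
        dates = [BASE, BASE + dt.timedelta(days=183)]
        assert meets_pair_rule(dates, 7, 183)
        assert not meets_pair_rule([BASE, BASE + dt.timedelta(days=184)], 7, 183)

    def test_agrees_with_brute_force_on_random_multisets(self):
        # independent oracle: exhaustive O(n^2) pair check
        rng = random.Random(7)
        for _ in range(50):
            n = rng.randint(0, 12)
            dates = sorted(
                BASE + dt.timedelta(days=rng.randint(0, 500)) for _ in range(n)
            )
            sep = rng.choice([0, 7, 30])
            window = rng.choice([None, 60, 183, 365])
            expected = any(
                sep <= (b - a).days and (window is None or (b - a).days <= window)
                for a, b in combinations(dates, 2)
            )
            assert meets_pair_rule(dates, sep, window) == expected


class TestAlgorithmDefinition:
    def test_needs_a_rule(self):
        with pytest.raises(ValueError, match="count rule"):
            AlgorithmDefinition(name="empty")

    def test_window_must_exceed_separation(self):
        with pytest.raises(ValueError, match="window_days"):
            AlgorithmDefinition(
                name="bad", oa_rule=CountRule("at_least", 2), window_days=7
            )

    def test_defaults_load(self, algorithms_by_name):
        assert len(algorithms_by_name) == 16
        assert algorithms_by_name["oa_ge2_6mo"].window_days == 183
        assert algorithms_by_name["oa_ge2_12mo_img"].require_imaging_within_days == 730

    def test_with_imaging_requirement(self, algorithms_by_name):
        base = algorithms_by_name["one_oa_code"]
        variant = base.with_imaging_requirement()
        assert variant.name == "one_oa_code_img"
        assert variant.require_imaging_within_days == 730


class TestApplyAlgorithm:
    def test_one_oa_code_positive(self, codesets, oa_code, algorithms_by_name):
        events = events_at(oa_code, [0])
        assert apply_algorithm(events, [], algorithms_by_name["one_oa_code"], codesets)

    def test_exactly_one_means_exactly(self, codesets, oa_code, algorithms_by_name):
        events = events_at(oa_code, [0, 400])
        assert not apply_algorithm(events, [], algorithms_by_name["one_oa_code"], codesets)

    def test_pair_within_six_months(self, codesets, oa_code, algorithms_by_name):
        events = events_at(oa_code, [0, 10])
        assert apply_algorithm(events, [], algorithms_by_name["oa_ge2_6mo"], codesets)

    def test_pair_outside_both_windows(self, codesets, oa_code, algorithms_by_name):
        events = events_at(oa_code, [0, 400])
        assert not apply_algorithm(events, [], algorithms_by_name["oa_ge2_6mo"], codesets)
        assert not apply_algorithm(events, [], algorithms_by_name["oa_ge2_12mo"], codesets)

    def test_pair_below_separation_fails(self, codesets, oa_code, algorithms_by_name):
        events = events_at(oa_code, [0, 5])
        assert not apply_algorithm(events, [], algorithms_by_name["oa_ge2_6mo"], codesets)

    def test_combination_rule(self, codesets, oa_code, pain_code, algorithms_by_name):
        events = events_at(oa_code, [0]) + events_at(pain_code, [30])
        assert apply_algorithm(events, [], algorithms_by_name["oa_and_pain_6mo"], codesets)

    def test_combination_same_day_fails_by_default(
        self, codesets, oa_code, pain_code, algorithms_by_name
    ):
        # default 7-day minimum separation also applies to the mixed rule
        events = events_at(oa_code, [0]) + events_at(pain_code, [0])
        assert not apply_algorithm(
            events, [], algorithms_by_name["oa_and_pain_6mo"], codesets
        )

    def test_combination_separation_configurable_to_zero(
        self, codesets, oa_code, pain_code
    ):
        algorithm = AlgorithmDefinition(
            name="mixed_same_day",
            oa_rule=CountRule("at_least", 1),
            pain_rule=CountRule("at_least", 1),
            window_days=183,
            min_separation_days=0,
        )
        events = events_at(oa_code, [0]) + events_at(pain_code, [0])
        assert apply_algorithm(events, [], algorithm, codesets)

    def test_imaging_requirement_symmetric_window(
        self, codesets, oa_code, algorithms_by_name
    ):
        algorithm = algorithms_by_name["one_oa_code_img"]
        events = events_at(oa_code, [0])

        def report(offset):
            return ImagingReport(
                "P1", BASE + dt.timedelta(days=offset), "xray",
                False, False, False, False, False,
            )

        assert apply_algorithm(events, [report(700)], algorithm, codesets)
        assert apply_algorithm(events, [report(-700)], algorithm, codesets)
        assert not apply_algorithm(events, [report(800)], algorithm, codesets)

    def test_imaging_requirement_met_by_imaging_code(
        self, codesets, oa_code, algorithms_by_name
    ):
        imaging_code = codesets.codes("imaging")[0]
        events = events_at(oa_code, [0]) + events_at(imaging_code, [100])
        assert apply_algorithm(events, [], algorithms_by_name["one_oa_code_img"], codesets)

    def test_gp_transcribed_report_does_not_count_as_documented_imaging(
        self, codesets, oa_code, algorithms_by_name
    ):
        report = ImagingReport(
            "P1", BASE, "xray", True, False, False, False, False, source="gp_transcribed"
        )
        events = events_at(oa_code, [0])
        assert not apply_algorithm(
            events, [report], algorithms_by_name["one_oa_code_img"], codesets
        )


def make_cohort(patients, events, questionnaires=None, imaging=None):
    return Cohort(
        patients={p.patient_id: p for p in patients},
        events=events,
        imaging=imaging or [],
        questionnaires=questionnaires or {},
    )


def answered(pid):
    return {pid: QuestionnaireResponse(pid, True, None)}


class TestExclusions:
    def test_single_gout_code_retained(self, codesets, oa_code):
        gout = codesets.codes("exclusion_gout")[0]
        cohort = make_cohort(
            [make_patient()],
            events_at(oa_code, [0]) + events_at(gout, [50]),
            answered("P1"),
        )
        retained, outcomes = apply_exclusions(cohort, codesets)
        assert "P1" in retained.patients
        assert not outcomes["P1"].excluded

    def test_gout_pair_seven_days_apart_excluded(self, codesets, oa_code):
        gout = codesets.codes("exclusion_gout")[0]
        cohort = make_cohort(
            [make_patient()],
            events_at(oa_code, [0]) + events_at(gout, [50, 57]),
            answered("P1"),
        )
        retained, outcomes = apply_exclusions(cohort, codesets)
        assert "P1" not in retained.patients
        assert outcomes["P1"].reason == "gout"

    def test_gout_pair_six_days_apart_retained(self, codesets, oa_code):
        gout = codesets.codes("exclusion_gout")[0]
        cohort = make_cohort(
            [make_patient()],
            events_at(oa_code, [0]) + events_at(gout, [50, 56]),
            answered("P1"),
        )
        retained, _ = apply_exclusions(cohort, codesets)
        assert "P1" in retained.patients

    def test_rheumatic_pair_counts_even_before_assessment_period(self, codesets, oa_code):
        # the two-code rheumatic rule looks at the whole record
        ra = codesets.codes("exclusion_ra")[0]
        cohort = make_cohort(
            [make_patient(start=dt.date(1998, 1, 1))],
            events_at(oa_code, [0])
            + events_at(ra, [0], base=dt.date(1999, 1, 1))
            + events_at(ra, [14], base=dt.date(1999, 1, 1)),
            answered("P1"),
        )
        _, outcomes = apply_exclusions(cohort, codesets)
        assert outcomes["P1"].reason == "ra"

    def test_tkr_before_index_excluded(self, codesets, oa_code):
        tkr = codesets.codes("tkr")[0]
        cohort = make_cohort(
            [make_patient()],
            events_at(oa_code, [0]) + events_at(tkr, [-100]),
            answered("P1"),
        )
        _, outcomes = apply_exclusions(cohort, codesets)
        assert outcomes["P1"].reason == "tkr_before_index"

    def test_tkr_after_index_retained(self, codesets, oa_code):
        tkr = codesets.codes("tkr")[0]
        cohort = make_cohort(
            [make_patient()],
            events_at(oa_code, [0]) + events_at(tkr, [100]),
            answered("P1"),
        )
        retained, _ = apply_exclusions(cohort, codesets)
        assert "P1" in retained.patients

    def test_insufficient_data_excluded(self, codesets, oa_code):
        cohort = make_cohort([make_patient()], events_at(oa_code, [0]))
        _, outcomes = apply_exclusions(cohort, codesets)
        assert outcomes["P1"].reason == "insufficient_data"

    def test_imaging_report_rescues_missing_questionnaire(self, codesets, oa_code):
        report = ImagingReport("P1", BASE, "xray", True, False, False, False, False)
        cohort = make_cohort([make_patient()], events_at(oa_code, [0]), imaging=[report])
        retained, _ = apply_exclusions(cohort, codesets)
        assert "P1" in retained.patients

    def test_reason_priority_ra_over_gout(self, codesets, oa_code):
        ra = codesets.codes("exclusion_ra")[0]
        gout = codesets.codes("exclusion_gout")[0]
        cohort = make_cohort(
            [make_patient()],
            events_at(oa_code, [0]) + events_at(gout, [10, 20]) + events_at(ra, [30, 40]),
            answered("P1"),
        )
        _, outcomes = apply_exclusions(cohort, codesets)
        assert outcomes["P1"].reason == "ra"

    def test_order_independence(self, codesets, oa_code):
        gout = codesets.codes("exclusion_gout")[0]
        patients = [make_patient(pid=f"P{i}") for i in range(1, 6)]
        events = []
        questionnaires = {}
        for i, p in enumerate(patients, start=1):
            events += events_at(oa_code, [0], pid=p.patient_id)
            if i % 2 == 0:
                events += events_at(gout, [10, 20], pid=p.patient_id)
            questionnaires.update(
                {p.patient_id: QuestionnaireResponse(p.patient_id, True, None)}
            )
        forward = make_cohort(patients, events, questionnaires)
        backward = make_cohort(list(reversed(patients)), list(reversed(events)), questionnaires)
        retained_f, _ = apply_exclusions(forward, codesets)
        retained_b, _ = apply_exclusions(backward, codesets)
        assert set(retained_f.patients) == set(retained_b.patients)


class TestEvaluateAll:
    def test_empty_cohort_gives_empty_matrix(self, codesets):
        matrix = evaluate_all(Cohort(), default_algorithms(), codesets)
        assert matrix.shape == (0, 16)

    def test_window_monotonicity_on_generated_cohort(self, codesets):
        cohort = generate_cohort(GeneratorParams(n_patients=300, seed=2), codesets)
        matrix = evaluate_all(cohort, default_algorithms(), codesets)
        for six, twelve in (
            ("oa_ge2_6mo", "oa_ge2_12mo"),
            ("pain_ge2_6mo", "pain_ge2_12mo"),
            ("oa_and_pain_6mo", "oa_and_pain_12mo"),
        ):
            assert (matrix[six] <= matrix[twelve]).all()

    def test_deterministic(self, codesets):
        cohort = generate_cohort(GeneratorParams(n_patients=100, seed=4), codesets)
        a = evaluate_all(cohort, default_algorithms(), codesets)
        b = evaluate_all(cohort, default_algorithms(), codesets)
        assert a.equals(b)

    def test_duplicate_algorithm_names_rejected(self, codesets, algorithms_by_name):
        algorithm = algorithms_by_name["one_oa_code"]
        with pytest.raises(ValueError, match="duplicate"):
            evaluate_all(Cohort(), [algorithm, algorithm], codesets)


def test_load_algorithms_rejects_non_list(tmp_path):
    path = tmp_path / "algos.yaml"
    path.write_text("name: solo\n")
    with pytest.raises(ValueError, match="list"):
        load_algorithms(path)


def test_eligibility_criteria_invariants():
    with pytest.raises(ValueError):
        EligibilityCriteria(min_age=90, max_age=40)
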