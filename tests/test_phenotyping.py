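"""Phenotyping algorithm tests: NLP-driven, structured, and ICD comparator."""

from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from divpheno import (
    Algorithm,
    Status,
    apply_exclusions,
    classify_icd_comparator,
    classify_nlp,
    classify_structured,
    compare_algorithms,
    compute_ppv,
    summarize_cohort,
)
from divpheno.phenotyping import PhenotypeAssignment

from conftest import make_record

D0 = date(2015, 6, 1)


class TestApplyExclusions:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            ([("ICD9CM", "556.1", D0)], True),
            ([("ICD9CM", "562.10", D0)], False),
            ([], False),
            ([("ICD9CM", "560.2", D0)], True),
            ([("ICD9CM", "560.1", D0)], False),  # prefix 560.2 must not catch 560.1
            ([("ICD10CM", "K51.90", D0)], True),
        ],
    )
    def test_prefix_matching(self, codes, expected):
        assert apply_exclusions(make_record(codes=codes)) is expected


class TestClassifyNlp:
    def test_positive_report_makes_diverticulosis_case(self):
        rec = make_record(report_texts=["Sigmoid diverticulosis."])
        a = classify_nlp(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CASE, Status.CONTROL)

    def test_negative_report_without_codes_is_control(self):
        rec = make_record(report_texts=["No diverticula. No masses."])
        a = classify_nlp(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CONTROL, Status.CONTROL)

    def test_no_reports_is_unclassified(self):
        a = classify_nlp(make_record())
        assert (a.diverticulosis, a.diverticulitis) == (Status.UNCLASSIFIED, Status.UNCLASSIFIED)

    def test_itis_mention_makes_both_cases(self):
        rec = make_record(report_texts=["Findings consistent with acute diverticulitis."])
        a = classify_nlp(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CASE, Status.CASE)

    def test_itis_code_promotes_nlp_osis_positive(self):
        rec = make_record(
            report_texts=["Sigmoid diverticulosis."],
            codes=[("ICD9CM", "562.11", D0)],
        )
        a = classify_nlp(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CASE, Status.CASE)

    def test_dd_code_blocks_control_status(self):
        # clean report but a diverticular code ever => not a trustworthy control
        rec = make_record(
            report_texts=["Normal colonoscopy to the cecum."],
            codes=[("ICD9CM", "562.10", D0)],
        )
        a = classify_nlp(rec)
        assert a.diverticulosis is Status.UNCLASSIFIED

    def test_exclusion_code_excludes(self):
        rec = make_record(
            report_texts=["Sigmoid diverticulosis."], codes=[("ICD9CM", "556.9", D0)]
        )
        a = classify_nlp(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.EXCLUDED, Status.EXCLUDED)

    def test_other_report_types_not_consulted(self):
        rec = make_record(report_texts=["diverticulitis"], report_type="other")
        assert classify_nlp(rec).diverticulosis is Status.UNCLASSIFIED


class TestClassifyStructured:
    def test_code_three_days_after_colonoscopy_is_case(self):
        rec = make_record(
            codes=[("ICD9CM", "562.10", D0 + timedelta(days=3))], proc_dates=[D0]
        )
        a = classify_structured(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CASE, Status.CONTROL)

    def test_code_ten_days_after_is_unclassified(self):
        rec = make_record(
            codes=[("ICD9CM", "562.10", D0 + timedelta(days=10))], proc_dates=[D0]
        )
        a = classify_structured(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.UNCLASSIFIED, Status.UNCLASSIFIED)

    @pytest.mark.parametrize("offset", [0, 7])
    def test_window_boundaries_inclusive(self, offset):
        rec = make_record(
            codes=[("ICD9CM", "562.11", D0 + timedelta(days=offset))], proc_dates=[D0]
        )
        a = classify_structured(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CASE, Status.CASE)

    def test_code_before_procedure_not_in_window(self):
        rec = make_record(
            codes=[("ICD9CM", "562.10", D0 - timedelta(days=1))], proc_dates=[D0]
        )
        assert classify_structured(rec).diverticulosis is not Status.CASE

    def test_procedure_without_codes_is_control(self):
        a = classify_structured(make_record(proc_dates=[D0]))
        assert (a.diverticulosis, a.diverticulitis) == (Status.CONTROL, Status.CONTROL)

    def test_nlp_positivity_merged_by_or(self):
        rec = make_record(
            report_texts=["Findings consistent with acute diverticulitis."],
            proc_dates=[D0],
        )
        a = classify_structured(rec)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CASE, Status.CASE)

    def test_positive_mention_blocks_control(self):
        rec = make_record(report_texts=["Sigmoid diverticulosis."], proc_dates=[D0])
        assert classify_structured(rec).diverticulosis is Status.CASE

    @given(shift=st.integers(min_value=-2000, max_value=2000),
           offset=st.integers(min_value=-20, max_value=30))
    @settings(max_examples=80, deadline=None)
    def test_invariant_to_global_date_shift(self, shift, offset):
        base = classify_structured(
            make_record(codes=[("ICD9CM", "562.10", D0 + timedelta(days=offset))], proc_dates=[D0])
        )
        shifted = classify_structured(
            make_record(
                codes=[("ICD9CM", "562.10", D0 + timedelta(days=offset + shift))],
                proc_dates=[D0 + timedelta(days=shift)],
            )
        )
        assert (base.diverticulosis, base.diverticulitis) == (
            shifted.diverticulosis,
            shifted.diverticulitis,
        )


class TestClassifyIcdComparator:
    def test_osis_code_maps_to_case(self, phecode_map):
        rec = make_record(codes=[("ICD9CM", "562.10", D0)])
        a = classify_icd_comparator(rec, phecode_map)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CASE, Status.CONTROL)

    def test_itis_code_maps_to_itis_case(self, phecode_map):
        rec = make_record(codes=[("ICD9CM", "562.11", D0)])
        a = classify_icd_comparator(rec, phecode_map)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CASE, Status.CASE)

    def test_exclusion_event_without_dd_is_excluded(self, phecode_map):
        rec = make_record(codes=[("ICD9CM", "556.9", D0)])
        a = classify_icd_comparator(rec, phecode_map)
        assert (a.diverticulosis, a.diverticulitis) == (Status.EXCLUDED, Status.EXCLUDED)

    def test_no_gi_events_is_control(self, phecode_map):
        a = classify_icd_comparator(make_record(), phecode_map)
        assert (a.diverticulosis, a.diverticulitis) == (Status.CONTROL, Status.CONTROL)

    def test_reports_never_consulted(self, phecode_map):
        rec = make_record(report_texts=["Severe diverticulitis everywhere."])
        assert classify_icd_comparator(rec, phecode_map).diverticulosis is Status.CONTROL


class TestSubsetInvariant:
    def test_itis_case_implies_osis_case_is_enforced(self):
        with pytest.raises(ValueError):
            PhenotypeAssignment("P1", Algorithm.NLP, Status.CONTROL, Status.CASE)

    def test_exclusion_applies_to_both(self):
        with pytest.raises(ValueError):
            PhenotypeAssignment("P1", Algorithm.NLP, Status.EXCLUDED, Status.CONTROL)


class TestComputePpv:
    def _assign(self, pid, osis):
        return PhenotypeAssignment(pid, Algorithm.NLP, osis, Status.CONTROL if osis is Status.CASE else osis)

    def test_perfect_concordance(self):
        assignments = [self._assign(f"P{i}", Status.CASE) for i in range(50)]
        gold = {f"P{i}": True for i in range(50)}
        rep = compute_ppv(assignments, gold)
        assert rep.ppv_case == 1.0 and rep.n_cases_reviewed == 50

    def test_nine_of_ten(self):
        assignments = [self._assign(f"P{i}", Status.CASE) for i in range(10)]
        gold = {f"P{i}": i > 0 for i in range(10)}
        assert compute_ppv(assignments, gold).ppv_case == pytest.approx(0.9)

    def test_empty_stratum_is_missing_not_zero(self):
        assignments = [self._assign("P0", Status.CASE)]
        rep = compute_ppv(assignments, {"P0": True})
        assert rep.ppv_control is None and rep.n_controls_reviewed == 0

    def test_unreviewed_patient_raises(self):
        with pytest.raises(KeyError):
            compute_ppv([], {"P9": True})


class TestCompareAlgorithms:
    def test_published_diverticulitis_overlap(self):
        rep = compare_algorithms(1265, 1201, n_overlap=1101)
        assert round(100 * rep.overlap_fraction_of_A, 1) == 87.0

    def test_identical_sets(self):
        rep = compare_algorithms({"a", "b"}, {"a", "b"})
        assert rep.fold_increase == 1.0 and rep.overlap_fraction_of_A == 1.0

    def test_disjoint_sets(self):
        rep = compare_algorithms({"a"}, {"b"})
        assert rep.overlap_fraction_of_A == 0.0

    def test_empty_b_fold_missing(self):
        assert compare_algorithms({"a"}, set()).fold_increase is None

    @given(
        a=st.sets(st.integers(0, 30), max_size=20),
        b=st.sets(st.integers(0, 30), max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_overlap_never_exceeds_either_count(self, a, b):
        rep = compare_algorithms(a, b)
        assert rep.n_overlap <= min(rep.n_A, rep.n_B)


def test_cohort_accounting_helper():
    s = summarize_cohort(3, 1)
    assert s["n_total"] == 4 and s["case_fraction_pct"] == pytest.approx(75.0)
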