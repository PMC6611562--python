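import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocburden.cohort import (
    Patient,
    baseline_utilization,
    charlson_score,
    find_index_date,
    is_continuously_enrolled,
    merge_stays,
    select_cohort,
)

from .conftest import make_claim, make_span

D = datetime.date


class TestIndexDate:
    def test_single_scd_claim(self, config):
        claims = [make_claim(start="2010-03-05", dx=("28241",))]
        assert find_index_date(claims, config) == D(2010, 3, 5)

    def test_claim_before_window_skipped(self, config):
        claims = [
            make_claim("C1", start="2009-06-15", dx=("28241",)),
            make_claim("C2", start="2009-08-01", dx=("28241",)),
        ]
        assert find_index_date(claims, config) == D(2009, 8, 1)

    def test_no_scd_claims(self, config):
        claims = [make_claim(dx=("4280",))]
        assert find_index_date(claims, config) is None

    def test_secondary_position_counts(self, config):
        claims = [make_claim(dx=("4280", "28260"))]
        assert find_index_date(claims, config) == D(2011, 1, 1)


def brute_force_enrolled(spans, interval):
    """Independent day-by-day coverage oracle."""
    covered = set()
    for s in spans:
        if s.medical and s.pharmacy:
            d = s.start
            while d <= s.end:
                covered.add(d)
                d += datetime.timedelta(days=1)
    d, hi = interval
    while d <= hi:
        if d not in covered:
            return False
        d += datetime.timedelta(days=1)
    return True


class TestContinuousEnrollment:
    def test_exact_cover(self):
        spans = [make_span(start="2010-01-01", end="2010-12-31")]
        assert is_continuously_enrolled(spans, (D(2010, 1, 1), D(2010, 12, 31)))

    def test_one_day_hole(self):
        spans = [
            make_span(start="2010-01-01", end="2010-06-14"),
            make_span(start="2010-06-16", end="2010-12-31"),
        ]
        assert not is_continuously_enrolled(spans, (D(2010, 1, 1), D(2010, 12, 31)))

    def test_abutting_spans_cover(self):
        # end d followed by start d+1: brute-force oracle confirms coverage
        spans = [
            make_span(start="2010-01-01", end="2010-06-15"),
            make_span(start="2010-06-16", end="2010-12-31"),
        ]
        interval = (D(2010, 1, 1), D(2010, 12, 31))
        assert brute_force_enrolled(spans, interval)
        assert is_continuously_enrolled(spans, interval)

    def test_medical_only_span_does_not_count(self):
        spans = [make_span(start="2010-01-01", end="2010-12-31", pharmacy=False)]
        assert not is_continuously_enrolled(spans, (D(2010, 2, 1), D(2010, 3, 1)))

    @settings(max_examples=150, deadline=None)
    @given(
        spans=st.lists(
            st.tuples(
                st.integers(0, 40), st.integers(0, 15),
                st.booleans(), st.booleans(),
            ),
            max_size=6,
        ),
        lo=st.integers(0, 40),
        length=st.integers(0, 20),
    )
    def test_matches_brute_force_oracle(self, spans, lo, length):
        origin = D(2010, 1, 1)
        day = lambda k: origin + datetime.timedelta(days=k)
        span_objs = [
            make_span(start=day(s).isoformat(), end=day(s + d).isoformat(),
                      medical=med, pharmacy=ph)
            for s, d, med, ph in spans
        ]
        interval = (day(lo), day(lo + length))
        assert is_continuously_enrolled(span_objs, interval) == brute_force_enrolled(
            span_objs, interval
        )


class TestCharlson:
    def test_no_mapped_codes(self):
        assert charlson_score([make_claim(dx=("78079",))]) == 0

    def test_chf_weight_one(self):
        # Deyo table: 428.x = congestive heart failure, weight 1
        assert charlson_score([make_claim(dx=("4280",))]) == 1

    def test_diabetes_hierarchy(self):
        # 250.0x (uncomplicated) + 250.4x (complicated): counted once, weight 2
        claims = [
            make_claim("C1", dx=("25000",)),
            make_claim("C2", dx=("25040",)),
        ]
        assert charlson_score(claims) == 2

    def test_category_counts_once(self):
        claims = [make_claim(f"C{i}", dx=("4280",)) for i in range(5)]
        assert charlson_score(claims) == 1

    def test_weight_six_categories(self):
        assert charlson_score([make_claim(dx=("042",))]) == 6
        assert charlson_score([make_claim(dx=("1970",))]) == 6

    def test_metastasis_supersedes_malignancy(self):
        claims = [make_claim("C1", dx=("1530",)), make_claim("C2", dx=("1970",))]
        assert charlson_score(claims) == 6

    def test_additive_across_categories(self):
        claims = [make_claim("C1", dx=("4280", "4912"))]  # CHF 1 + COPD 1
        assert charlson_score(claims) == 2


class TestBaselineUtilization:
    def test_same_day_er_claims_dedup(self):
        claims = [
            make_claim("C1", start="2010-01-05", place="ER"),
            make_claim("C2", start="2010-01-05", place="ER"),
        ]
        er, ip, los = baseline_utilization(claims)
        assert (er, ip, los) == (1, 0, 0)

    def test_single_stay_los(self):
        claims = [make_claim(start="2010-01-01", end="2010-01-05", place="inpatient")]
        er, ip, los = baseline_utilization(claims)
        assert (er, ip, los) == (0, 1, 4)

    def test_overlapping_stays_merge(self):
        # brute-force interval union: [01-01..01-03] U [01-03..01-06] = one
        # stay 01-01..01-06, LOS 5
        claims = [
            make_claim("C1", start="2010-01-01", end="2010-01-03", place="inpatient"),
            make_claim("C2", start="2010-01-03", end="2010-01-06", place="inpatient"),
        ]
        er, ip, los = baseline_utilization(claims)
        assert (er, ip, los) == (0, 1, 5)

    def test_same_day_stay_counts_one_day(self):
        claims = [make_claim(start="2010-01-01", place="inpatient")]
        assert baseline_utilization(claims) == (0, 1, 1)

    def test_abutting_stays_merge(self):
        claims = [
            make_claim("C1", start="2010-01-01", end="2010-01-03", place="inpatient"),
            make_claim("C2", start="2010-01-04", end="2010-01-06", place="inpatient"),
        ]
        assert baseline_utilization(claims) == (0, 1, 5)

    def test_separated_stays_stay_separate(self):
        claims = [
            make_claim("C1", start="2010-01-01", end="2010-01-03", place="inpatient"),
            make_claim("C2", start="2010-01-10", end="2010-01-12", place="inpatient"),
        ]
        assert baseline_utilization(claims) == (0, 2, 4)


def _patient(pid="P1", birth="1980-06-15"):
    return Patient(pid, D.fromisoformat(birth), "F", "Black", "Northeast")


def _basic_inputs(pid="P1"):
    patients = [_patient(pid)]
    spans = [make_span(patient_id=pid)]
    claims = [make_claim("C1", pid, start="2010-03-05", dx=("28241",))]
    return patients, spans, claims


class TestSelectCohort:
    def test_clean_patient_selected(self, config):
        patients, spans, claims = _basic_inputs()
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert len(members) == 1 and not exclusions
        m = members[0]
        assert m.index_date == D(2010, 3, 5)
        assert m.followup_end == D(2013, 12, 31)
        assert m.followup_end <= config.study_end
        assert m.age_at_index == 29

    def test_trial_code_excluded(self, config):
        patients, spans, claims = _basic_inputs()
        claims.append(make_claim("C2", "P1", start="2011-05-01", dx=("V707",)))
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert not members
        assert exclusions[0].excluded_reason == "trial_code"

    def test_dual_eligibility_excluded(self, config):
        patients, spans, claims = _basic_inputs()
        spans = [make_span(dual=True)]
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert exclusions[0].excluded_reason == "dual_eligible"

    def test_under_age_excluded(self, config):
        patients, spans, claims = _basic_inputs()
        patients = [_patient(birth="1995-01-01")]  # 15 at index
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert exclusions[0].excluded_reason == "under_age"

    def test_no_scd_claim(self, config):
        patients, spans, claims = _basic_inputs()
        claims = [make_claim("C1", start="2010-03-05", dx=("4280",))]
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert exclusions[0].excluded_reason == "no_scd_claim_in_window"

    def test_baseline_gap_excluded(self, config):
        patients, _, claims = _basic_inputs()
        spans = [
            make_span(start="2009-01-01", end="2010-01-15"),
            make_span(start="2010-01-20", end="2013-12-31"),
        ]
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert exclusions[0].excluded_reason == "insufficient_baseline"

    def test_followup_gap_excluded_and_order(self, config):
        # follow-up coverage stops 100 days after index
        patients, _, claims = _basic_inputs()
        spans = [make_span(start="2009-01-01", end="2010-06-13")]
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert exclusions[0].excluded_reason == "insufficient_followup"

    def test_latest_feasible_index_boundary(self, config):
        # index on the last identification day still fits 365 follow-up days
        patients = [_patient()]
        spans = [make_span()]
        claims = [make_claim("C1", start="2012-12-31", dx=("28241",))]
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert len(members) == 1
        assert members[0].followup_days == 365

    def test_partition_invariant(self, config):
        patients = [_patient(f"P{i}") for i in range(4)]
        spans = [make_span(patient_id=f"P{i}") for i in range(4)]
        claims = [
            make_claim("C1", "P0", start="2010-03-05", dx=("28241",)),
            make_claim("C2", "P1", start="2010-03-05", dx=("4280",)),
            make_claim("C3", "P2", start="2010-03-05", dx=("28242",)),
            make_claim("C4", "P3", start="2013-06-01", dx=("28241",)),  # outside window
        ]
        members, exclusions = select_cohort(patients, spans, claims, config)
        assert len(members) + len(exclusions) == len(patients)
        seen = {m.patient_id for m in members} | {e.patient_id for e in exclusions}
        assert seen == {p.patient_id for p in patients}

    def test_duplicate_patient_id_rejected(self, config):
        patients = [_patient("P1"), _patient("P1")]
        with pytest.raises(ValueError, match="duplicate"):
            select_cohort(patients, [], [], config)

    def test_followup_relaxation_monotonicity(self, config):
        import dataclasses

        patients, _, claims = _basic_inputs()
        spans = [make_span(start="2009-01-01", end="2010-09-01")]
        strict = select_cohort(patients, spans, claims, config)[0]
        relaxed_cfg = dataclasses.replace(config, followup_min_days=120)
        relaxed = select_cohort(patients, spans, claims, relaxed_cfg)[0]
        assert len(relaxed) >= len(strict)

    def test_followup_end_truncates_at_disenrollment(self, config):
        patients, _, claims = _basic_inputs()
        spans = [make_span(start="2009-01-01", end="2011-06-30")]
        members, _ = select_cohort(patients, spans, claims, config)
        assert members[0].followup_end == D(2011, 6, 30)
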