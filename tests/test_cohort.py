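"""Cohort selection, prenatal-visit identification, exclusions, validation."""

from datetime import date

import pytest

from matcvrisk.catalog import default_catalog
from matcvrisk.cohort import (
    CohortCriteria,
    ConfigurationError,
    RecordValidationError,
    apply_exclusions,
    collect_prenatal_visits,
    extract,
    select_delivery_cohort,
    validate_extraction,
)
from tests.conftest import delivery_rows, person, prenatal_rows, tiny_raw


def _cohort_fixture():
    v1, d1 = delivery_rows("P1", "V1", "2018-06-01")  # in window
    v2, d2 = delivery_rows("P2", "V2", "2021-01-01")  # outside window
    v3 = ("V3", "P3", "2018-05-01 09:00", "clinic appointment")  # no delivery
    return tiny_raw(
        persons=[person("P1"), person("P2"), person("P3")],
        visits=[v1, v2, v3],
        diagnoses=d1 + d2,
    )


def test_delivery_window_is_inclusive_and_required():
    records = _cohort_fixture()
    cohort = select_delivery_cohort(records, CohortCriteria())
    assert cohort == {"P1"}  # P2 outside window, P3 has no delivery


def test_window_boundary_dates_included():
    v1, d1 = delivery_rows("P1", "V1", "2017-01-01")
    v2, d2 = delivery_rows("P2", "V2", "2020-12-31")
    records = tiny_raw(persons=[person("P1"), person("P2")], visits=[v1, v2], diagnoses=d1 + d2)
    assert select_delivery_cohort(records, CohortCriteria()) == {"P1", "P2"}


def test_malformed_delivery_dates_raise_with_rows():
    v1, d1 = delivery_rows("P1", "V1", "2018-06-01")
    d1[0] = (d1[0][0], d1[0][1], d1[0][2], d1[0][3], d1[0][4], "not-a-date")
    records = tiny_raw(persons=[person("P1")], visits=[v1], diagnoses=d1)
    with pytest.raises(RecordValidationError):
        select_delivery_cohort(records, CohortCriteria())


def test_prenatal_visit_selection_rules():
    dv, ddx = delivery_rows("P1", "VD", "2018-06-01")
    pv1, pdx1 = prenatal_rows("P1", "VP1", "2018-02-01")  # listed code, before delivery
    pv2 = ("VP2", "P1", "2018-03-01 09:00", "clinic appointment")  # no listed code
    dx2 = [("VP2", "P1", "J06.9", "ICD-10-CM", "encounter", "2018-03-01 09:00")]
    pv3, pdx3 = prenatal_rows("P2", "VP3", "2018-02-15")  # not in cohort
    records = tiny_raw(
        persons=[person("P1"), person("P2")],
        visits=[dv, pv1, pv2, pv3],
        diagnoses=ddx + pdx1 + dx2 + pdx3,
    )
    criteria = CohortCriteria()
    got = collect_prenatal_visits(records, {"P1"}, criteria)
    assert got == {"VP1", "VD"}  # delivery visit carries its own encounter code


def test_visits_after_delivery_not_collected():
    dv, ddx = delivery_rows("P1", "VD", "2018-06-01")
    pv, pdx = prenatal_rows("P1", "VP", "2018-07-01")  # dated after delivery
    records = tiny_raw(persons=[person("P1")], visits=[dv, pv], diagnoses=ddx + pdx)
    assert collect_prenatal_visits(records, {"P1"}, CohortCriteria()) == {"VD"}


def test_empty_prenatal_code_list_is_config_error():
    records = _cohort_fixture()
    with pytest.raises(ConfigurationError):
        collect_prenatal_visits(records, {"P1"}, CohortCriteria(prenatal_code_list=()))


def test_year_1900_visits_excluded():
    pv, pdx = prenatal_rows("P1", "V1900", "1900-01-01")
    records = tiny_raw(persons=[person("P1")], visits=[pv], diagnoses=pdx)
    kept, report = apply_exclusions(records, {"V1900"}, CohortCriteria())
    assert kept == set()
    assert "registration_year" in report.excluded["reasons"].iloc[0]


def test_communication_visit_excluded_only_without_clinical_events():
    pv1 = ("VC1", "P1", "2018-03-01 09:00", "portal message")
    pv2 = ("VC2", "P1", "2018-03-02 09:00", "portal message")
    ev = [("E1", "VC2", "P1", "systolic blood pressure", "118", "mm Hg", "2018-03-02 09:00")]
    records = tiny_raw(persons=[person("P1")], visits=[pv1, pv2], events=ev)
    kept, report = apply_exclusions(records, {"VC1", "VC2"}, CohortCriteria())
    assert kept == {"VC2"}  # same type, but carries a qualifying clinical event
    assert report.tally() == {"communication_no_clinical_data": 1}


@pytest.mark.parametrize(
    "age,included", [(17, False), (18, True), (35, True), (36, False)]
)
def test_age_boundaries_inclusive_18_to_35(age, included):
    visit_date = date(2018, 3, 1)
    dob = date(visit_date.year - age, visit_date.month, visit_date.day)
    pv, pdx = prenatal_rows("P1", "VA", visit_date.isoformat())
    records = tiny_raw(persons=[person("P1", dob=dob.isoformat())], visits=[pv], diagnoses=pdx)
    kept, _ = apply_exclusions(records, {"VA"}, CohortCriteria())
    assert (kept == {"VA"}) is included


def test_birthday_on_visit_day_counts_as_completed_year():
    # turns 36 exactly on the visit day -> excluded; the day before -> included
    pv, _ = prenatal_rows("P1", "VB", "2018-03-01")
    records = tiny_raw(persons=[person("P1", dob="1982-03-01")], visits=[pv])
    kept, _ = apply_exclusions(records, {"VB"}, CohortCriteria())
    assert kept == set()
    records = tiny_raw(persons=[person("P1", dob="1982-03-02")], visits=[pv])
    kept, _ = apply_exclusions(records, {"VB"}, CohortCriteria())
    assert kept == {"VB"}


def test_missing_dob_routed_to_review_not_dropped():
    pv, _ = prenatal_rows("P1", "VR", "2018-03-01")
    records = tiny_raw(persons=[person("P1", dob="")], visits=[pv])
    kept, report = apply_exclusions(records, {"VR"}, CohortCriteria())
    assert kept == {"VR"}
    assert list(report.review["issue"]) == ["missing_or_malformed_dob"]


def test_exclusion_criteria_are_order_independent(dataset):
    """Each exclusion is a per-visit predicate: the removal set equals the
    union of single-criterion removal sets, so order cannot matter."""
    _, records, _ = dataset
    criteria = CohortCriteria()
    cohort = select_delivery_cohort(records, criteria)
    candidates = collect_prenatal_visits(records, cohort, criteria)
    _, full = apply_exclusions(records, candidates, criteria)
    removed_full = set(full.excluded["visit_id"])

    neutral = dict(
        excluded_registration_years=(),
        excluded_visit_types=(),
        age_min=0,
        age_max=200,
    )
    union = set()
    for active in (
        {"excluded_registration_years": (1900,)},
        {"excluded_visit_types": ("portal message", "phone call")},
        {"age_min": 18, "age_max": 35},
    ):
        single = CohortCriteria(**{**neutral, **active})
        _, rep = apply_exclusions(records, candidates, single)
        union |= set(rep.excluded["visit_id"])
    assert union == removed_full


def test_extraction_is_idempotent(dataset):
    _, records, _ = dataset
    _, included_1, _ = extract(records)
    _, included_2, _ = extract(records)
    assert included_1 == included_2


def test_validation_report_flags_missing_and_unknown():
    pv, pdx = prenatal_rows("P1", "VV", "2018-03-01")
    ev = [("E1", "VV", "P1", "serum rhubarb", "5", "mg", "2018-03-01 09:00")]
    records = tiny_raw(persons=[person("P1")], visits=[pv], events=ev, diagnoses=pdx)
    report = validate_extraction(records, {"VV"}, default_catalog(), sample_size=5, seed=3)
    assert "systolic_blood_pressure" in report.missing_variables
    assert "serum rhubarb" in report.uncategorized_labels
    report_again = validate_extraction(records, {"VV"}, default_catalog(), sample_size=5, seed=3)
    assert report.sampled_visits.equals(report_again.sampled_visits)
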