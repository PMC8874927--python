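"""Category triples, unit normalization, final schema and catalog."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matcvrisk.deidentify import DeidRecordSet
from matcvrisk.harmonize import (
    KG_PER_LB,
    SchemaIntegrityError,
    assemble_schema,
    categorize_record,
    default_mapping_rules,
    normalize_value,
)


@pytest.mark.parametrize(
    "table,label,expected",
    [
        ("event", "hemoglobin", ("event", "labs", "hematology")),
        ("event", "systolic blood pressure", ("event", "measurements", "vitals")),
        ("event", "weight", ("event", "measurements", "weight and BMI")),
        ("event", "chest pain", ("event", "symptoms", "")),
        ("event", "prepregnancy diagnosis of diabetes", ("event", "history", "")),
        ("diagnosis", "admitting diagnosis", ("diagnosis", "admitting diagnosis", "")),
        ("diagnosis", "discharge", ("diagnosis", "discharge diagnosis", "")),
    ],
)
def test_categorize_known_labels(table, label, expected):
    triple = categorize_record(table, label, default_mapping_rules())
    assert (triple.category, triple.sub_category, triple.clinical_cat) == expected


def test_unknown_label_goes_to_review_queue():
    assert categorize_record("event", "serum rhubarb", default_mapping_rules()) is None


@pytest.mark.parametrize(
    "value,unit,expected_value,expected_unit,flagged",
    [
        (154.324, "lb", 70.00, "kg", False),
        (70, "kg", 70.0, "kg", False),
        (120, "mm Hg", 120.0, "mm Hg", False),
        (120, "furlongs", 120.0, "furlongs", True),
    ],
)
def test_normalize_value_cases(value, unit, expected_value, expected_unit, flagged):
    norm = normalize_value(value, unit)
    assert norm.value == pytest.approx(expected_value, abs=1e-9)
    assert norm.unit == expected_unit
    assert norm.flagged is flagged


def test_blank_presence_record_passes_unflagged():
    norm = normalize_value("", "")
    assert norm.value is None and not norm.flagged


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=500.0, allow_nan=False))
def test_normalize_idempotent_and_round_trip(pounds):
    once = normalize_value(pounds, "lb")
    twice = normalize_value(once.value, once.unit)
    assert (twice.value, twice.unit) == (once.value, once.unit)
    # lb -> kg (rounded to 0.01 kg) -> lb recovers the input within 0.02 lb
    assert abs(once.value / KG_PER_LB - pounds) <= 0.02


def _tiny_deid() -> DeidRecordSet:
    persons = pd.DataFrame(
        [("aa11", 28, "White", "urban")],
        columns=["person_id", "age_at_index", "race", "urbanicity"],
    )
    visits = pd.DataFrame(
        [("vv11", "aa11", 0, "09:00", "clinic appointment")],
        columns=["visit_id", "person_id", "day_offset", "time_of_day", "visit_type"],
    )
    events = pd.DataFrame(
        [
            ("aa11", "vv11", "systolic blood pressure", "120", "mm Hg", 0, "09:00"),
            ("aa11", "vv11", "systolic blood pressure", "120", "mm Hg", 0, "09:00"),  # duplicate
            ("aa11", "vv11", "weight", "154.324", "lb", 0, "09:01"),
            ("aa11", "vv11", "serum rhubarb", "5", "mg", 0, "09:02"),
        ],
        columns=["person_id", "visit_id", "event_label", "result_value", "result_unit", "day_offset", "time_of_day"],
    )
    diagnoses = pd.DataFrame(
        [("aa11", "vv11", "Z34.90", "ICD-10-CM", "encounter", 0, "09:00")],
        columns=["person_id", "visit_id", "code", "code_system", "diagnosis_type", "day_offset", "time_of_day"],
    )
    familyhx = pd.DataFrame([("aa11", "family history of diabetes")], columns=["person_id", "item"])
    return DeidRecordSet(persons, visits, events, diagnoses, familyhx)


def test_assemble_schema_tables_catalog_and_review():
    tables, catalog, review = assemble_schema(_tiny_deid())
    # visit-grain tables carry both ids; person-grain tables do not
    for name in ("event", "diagnosis", "visit"):
        cols = getattr(tables, name).columns
        assert "person_id" in cols and "visit_id" in cols
    assert "visit_id" not in tables.familyhx.columns
    assert "visit_id" not in tables.race.columns
    # catalog covers every emitted field exactly once
    total_fields = sum(len(getattr(tables, n).columns) for n in tables._TABLES)
    assert len(catalog) == total_fields
    # categorization is total: categorized + review == input rows (after dedup)
    assert len(review) == 1 and review["label"].iloc[0] == "serum rhubarb"
    assert len(tables.event) == 2  # duplicate collapsed, rhubarb queued
    # weight normalized to canonical kg
    weight = tables.event[tables.event["event_label"] == "weight"]
    assert weight["unit"].iloc[0] == "kg"
    assert weight["value"].iloc[0] == pytest.approx(70.00)


def test_orphan_event_rows_are_integrity_errors():
    deid = _tiny_deid()
    deid.events.loc[0, "visit_id"] = "missing-visit"
    with pytest.raises(SchemaIntegrityError):
        assemble_schema(deid)


def test_pipeline_schema_catalog_complete(pipeline_out):
    catalog = pd.read_csv(pipeline_out / "harmonized" / "catalog.csv")
    for name in ("person", "visit", "event", "diagnosis", "familyhx", "race"):
        table = pd.read_csv(pipeline_out / "harmonized" / f"{name}.csv", keep_default_na=False)
        fields = set(catalog.loc[catalog["table"] == name, "field"])
        assert fields == set(table.columns)
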