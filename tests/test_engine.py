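"""Risk engine: triggers, encounter rule, chronology, baseline, classification."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matcvrisk.catalog import RiskCatalog, RiskFactorDef, default_catalog
from matcvrisk.engine import (
    LEVEL_NONE,
    LEVEL_RED_FLAG,
    LEVEL_STANDARD,
    ContractError,
    ErrorLedger,
    RiskFinding,
    add_classification,
    assess_encounter,
    classify_event,
    compute_baseline,
    default_classification_table,
    evaluate_numeric,
    evaluate_presence,
    evaluate_static,
    run_patient,
)

CATALOG = default_catalog()


@pytest.mark.parametrize(
    "quantity,value,expected",
    [
        ("systolic_blood_pressure", 160, LEVEL_RED_FLAG),
        ("systolic_blood_pressure", 139, None),
        ("heart_rate", 112, LEVEL_STANDARD),
        ("oxygen_saturation", 95, LEVEL_STANDARD),
        ("oxygen_saturation", 94, LEVEL_RED_FLAG),
    ],
)
def test_numeric_trigger_examples(quantity, value, expected):
    finding = evaluate_numeric(quantity, value, CATALOG.by_quantity(quantity))
    if expected is None:
        assert finding is None
    else:
        assert finding.level == expected


def test_quantity_definition_mismatch_is_contract_error():
    with pytest.raises(ContractError):
        evaluate_numeric("heart_rate", 100, CATALOG.by_quantity("systolic_blood_pressure"))


@pytest.mark.parametrize(
    "label,expected",
    [
        ("dyspnea", LEVEL_RED_FLAG),
        ("orthopnea", LEVEL_RED_FLAG),
        ("chest pain", LEVEL_STANDARD),
        ("common cold", None),
    ],
)
def test_presence_trigger_examples(label, expected):
    finding = evaluate_presence(label, CATALOG)
    if expected is None:
        assert finding is None
    else:
        assert finding.level == expected


@pytest.mark.parametrize(
    "age,race,history,bmi,expected_ids",
    [
        (28, "White", [], 35.0, {"prepregnancy_obesity"}),
        (28, "White", [], 34.9, set()),
        (28, "White", ["prepregnancy diagnosis of hypertension"], None, {"prepregnancy_hypertension"}),
        (40, "African American", [], None, {"age_40_or_older", "race_african_american"}),
    ],
)
def test_static_findings(age, race, history, bmi, expected_ids):
    findings = evaluate_static(age, race, history, bmi, CATALOG)
    assert {f.factor_id for f in findings} == expected_ids


def _finding(i, level=LEVEL_STANDARD):
    return RiskFinding(f"f{i}", level)


@pytest.mark.parametrize(
    "findings,expected",
    [
        ([], LEVEL_NONE),
        ([_finding(1)], LEVEL_STANDARD),
        ([_finding(1), _finding(2), _finding(3)], LEVEL_STANDARD),
        ([_finding(1), _finding(2), _finding(3), _finding(4)], LEVEL_RED_FLAG),
        ([_finding(1, LEVEL_RED_FLAG)], LEVEL_RED_FLAG),
    ],
)
def test_encounter_rule(findings, expected):
    level, _ = assess_encounter(findings)
    assert level == expected


def test_duplicate_factor_ids_count_once():
    # the same symptom coded twice is one risk factor, not two
    findings = [_finding(1), _finding(1), _finding(2), _finding(3)]
    level, deduped = assess_encounter(findings)
    assert level == LEVEL_STANDARD and len(deduped) == 3
    # the more severe level wins for a duplicated factor
    level, deduped = assess_encounter([_finding(1), _finding(1, LEVEL_RED_FLAG)])
    assert level == LEVEL_RED_FLAG and len(deduped) == 1


_LEVELS = {LEVEL_NONE: 0, LEVEL_STANDARD: 1, LEVEL_RED_FLAG: 2}


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 6), st.sampled_from([LEVEL_STANDARD, LEVEL_RED_FLAG])),
        max_size=8,
    ),
    st.tuples(st.integers(0, 6), st.sampled_from([LEVEL_STANDARD, LEVEL_RED_FLAG])),
)
def test_adding_a_finding_never_lowers_the_level(findings, extra):
    base = [RiskFinding(f"f{i}", lvl) for i, lvl in findings]
    level_before, _ = assess_encounter(base)
    level_after, _ = assess_encounter(base + [RiskFinding(f"f{extra[0]}", extra[1])])
    assert _LEVELS[level_after] >= _LEVELS[level_before]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(60, 220), st.floats(0, 40))
def test_raising_a_value_in_trigger_direction_never_lowers_finding(value, bump):
    definition = CATALOG.by_quantity("systolic_blood_pressure")
    before = evaluate_numeric("systolic_blood_pressure", value, definition)
    after = evaluate_numeric("systolic_blood_pressure", value + bump, definition)
    rank = lambda f: 0 if f is None else _LEVELS[f.level]
    assert rank(after) >= rank(before)


def _timeline(rows):
    visits = pd.DataFrame(
        [(f"v{i}", day, time) for i, (day, time, *_rest) in enumerate(rows)],
        columns=["visit_id", "day_offset", "time_of_day"],
    )
    events = []
    for i, (day, time, observations) in enumerate(rows):
        for label, value, unit in observations:
            events.append((f"v{i}", label, value, unit, day, time, False))
    events = pd.DataFrame(
        events,
        columns=["visit_id", "event_label", "value", "unit", "day_offset", "time_of_day", "needs_review"],
    )
    return visits, events


def test_run_patient_onsets_and_chronology():
    visits, events = _timeline(
        [
            (0, "09:00", [("systolic blood pressure", 120.0, "mm Hg")]),
            (30, "09:00", [("systolic blood pressure", 145.0, "mm Hg")]),
            (45, "09:00", [("systolic blood pressure", 165.0, "mm Hg")]),
        ]
    )
    profiles, onsets = run_patient("p", visits, events, [], CATALOG)
    assert [p.level for p in profiles] == [LEVEL_NONE, LEVEL_STANDARD, LEVEL_RED_FLAG]
    assert onsets == {"standard": 30, "red_flag": 45}
    # unordered input is sorted internally; output is deterministic
    shuffled = visits.iloc[[2, 0, 1]].reset_index(drop=True)
    profiles_2, onsets_2 = run_patient("p", shuffled, events, [], CATALOG)
    assert onsets_2 == onsets
    assert [p.visit_id for p in profiles_2] == [p.visit_id for p in profiles]


def test_run_patient_all_normal_has_no_onsets():
    visits, events = _timeline(
        [(0, "09:00", [("systolic blood pressure", 110.0, "mm Hg")])]
    )
    _, onsets = run_patient("p", visits, events, [], CATALOG)
    assert onsets == {"standard": None, "red_flag": None}


def test_static_findings_active_at_every_encounter():
    visits, events = _timeline(
        [(0, "09:00", [("heart rate", 80.0, "bpm")]), (10, "09:00", [("heart rate", 82.0, "bpm")])]
    )
    statics = [RiskFinding("prepregnancy_obesity", LEVEL_STANDARD)]
    profiles, onsets = run_patient("p", visits, events, statics, CATALOG)
    assert all(p.level == LEVEL_STANDARD for p in profiles)
    assert onsets["standard"] == 0


def test_flagged_events_do_not_trigger_findings():
    visits, events = _timeline(
        [(0, "09:00", [("systolic blood pressure", 170.0, "mm Hg")])]
    )
    events["needs_review"] = True
    _, onsets = run_patient("p", visits, events, [], CATALOG)
    assert onsets == {"standard": None, "red_flag": None}


def test_baseline_median_and_norm_conformance():
    obs = pd.DataFrame(
        {
            "quantity": ["systolic_blood_pressure"] * 4,
            "value": [98.0, 100.0, 104.0, 150.0],
            "day_offset": [0, 10, 20, 30],
            "time_of_day": ["09:00"] * 4,
        }
    )
    baseline = compute_baseline(obs, k=3, norms={"systolic_blood_pressure": (90.0, 139.0)})
    assert baseline.values["systolic_blood_pressure"] == 100.0  # median of first 3
    assert baseline.conforms
    high = obs.assign(value=[165.0, 166.0, 167.0, 150.0])
    flagged = compute_baseline(high, k=3, norms={"systolic_blood_pressure": (90.0, 139.0)})
    assert not flagged.conforms
    # fewer than k observations: no baseline, catalog thresholds apply
    sparse = compute_baseline(obs.head(2), k=3)
    assert sparse.values == {}


def test_baseline_mode_disabled_equals_catalog_thresholds(pipeline_out):
    from matcvrisk.engine import assess_cohort
    from matcvrisk.harmonize import HarmonizedRecordSet

    tables = HarmonizedRecordSet.from_csv(pipeline_out / "harmonized")
    profiles_a, onsets_a = assess_cohort(tables, baseline_mode=False)
    profiles_b, onsets_b = assess_cohort(tables, baseline_mode=False)
    assert profiles_a.equals(profiles_b) and onsets_a.equals(onsets_b)


def test_classification_review_and_extend_loop():
    table = default_classification_table()
    ledger = ErrorLedger()
    assert classify_event("organ failure", table, ledger) is None
    assert ledger.entries == ["organ failure"]
    table = add_classification(table, "organ failure", "organ failure risk")
    ledger_2 = ErrorLedger()
    assert classify_event("organ failure", table, ledger_2) == "organ failure risk"
    assert ledger_2.entries == []
    assert classify_event("heart rate", table, ledger_2) == "vital sign"


def test_catalog_rejects_inconsistent_red_flag_threshold():
    with pytest.raises(ValueError):
        RiskFactorDef(
            id="bad",
            kind="physical_finding",
            persistence="variable",
            trigger="numeric",
            quantity="q",
            direction="ge",
            standard_threshold=140.0,
            red_flag_threshold=120.0,
        )


def test_catalog_rejects_duplicate_ids():
    f = CATALOG.factors[0]
    with pytest.raises(ValueError):
        RiskCatalog(factors=[f, f])
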