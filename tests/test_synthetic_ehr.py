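"""Generator contracts: determinism, planted structure, ground-truth consistency."""

import math
from datetime import date

import pandas as pd
import pytest

from matcvrisk.catalog import default_catalog
from matcvrisk.synthetic_ehr import (
    ConfigurationError,
    GeneratorConfig,
    generate_cohort,
    generate_dataset,
    inject_artifacts,
)


def test_every_patient_has_a_delivery_in_window():
    config = GeneratorConfig(n_patients=100, seed=7)
    records, _ = generate_cohort(config)
    assert len(records.persons) == 100
    proc = records.diagnoses[records.diagnoses["diagnosis_type"] == "procedure"]
    assert set(proc["person_id"]) == set(records.persons["person_id"])
    days = pd.to_datetime(proc["diagnosis_datetime"]).dt.date
    lo, hi = config.date_window
    assert ((days >= lo) & (days <= hi)).all()


def test_same_seed_gives_byte_identical_output():
    config = GeneratorConfig(n_patients=50, seed=7)
    a, truth_a = generate_dataset(config)
    b, truth_b = generate_dataset(config)
    for name in ("persons", "visits", "events", "diagnoses", "family_history"):
        assert getattr(a, name).to_csv(index=False) == getattr(b, name).to_csv(index=False)
    assert truth_a.patients.to_csv(index=False) == truth_b.patients.to_csv(index=False)
    assert truth_a.artifact_visits.to_csv(index=False) == truth_b.artifact_visits.to_csv(index=False)


@pytest.mark.parametrize(
    "column,expected_p,kwargs",
    [
        ("red_flag", 0.2, {"frac_red_flag": 0.2, "frac_with_risk": 0.4}),
        ("delivery_first", 0.4583, {}),
        ("single_visit", 0.3544, {}),
    ],
)
def test_planted_proportions_within_binomial_bounds(column, expected_p, kwargs):
    """Planted fractions are recovered within 3 SD of the binomial at n=500."""
    n = 500
    config = GeneratorConfig(n_patients=n, seed=1, **kwargs)
    _, truth = generate_cohort(config)
    if column == "red_flag":
        observed = (truth.patients["risk_class"] == "red_flag").sum()
    else:
        observed = (truth.patients["category"] == column).sum()
    sd = math.sqrt(n * expected_p * (1 - expected_p))
    assert abs(observed - n * expected_p) <= 3 * sd


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_patients": 0},
        {"frac_with_risk": 1.2},
        {"frac_red_flag": 0.5, "frac_with_risk": 0.2},
        {"frac_single_visit": 0.7, "frac_delivery_first_visit": 0.7},
        {"date_window": (date(2020, 1, 1), date(2019, 1, 1))},
        {"mean_visits_per_patient": 0.0},
        {"lead_time_min_days": 30, "lead_time_max_days": 7},
    ],
)
def test_invalid_configuration_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        GeneratorConfig(**kwargs).validate()


def test_zero_artifact_fraction_is_noop():
    config = GeneratorConfig(n_patients=30, seed=2, frac_artifact_visits=0.0)
    records, truth = generate_cohort(config)
    out = inject_artifacts(records, config, truth)
    assert out.visits.to_csv(index=False) == records.visits.to_csv(index=False)
    assert len(truth.artifact_visits) == 0


def test_injected_artifacts_marked_and_structured(dataset):
    _, records, truth = dataset
    art = truth.artifact_visits
    assert len(art) > 0
    merged = art.merge(records.visits, on="visit_id")
    hist = merged[merged["artifact_type"] == "historical_upload"]
    assert (hist["registration_datetime"].str.startswith("1900")).all()
    comm = merged[merged["artifact_type"] == "communication"]
    assert set(comm["visit_type"]) <= {"portal message", "phone call"}
    # communication (and upload) visits carry zero clinical events
    assert not records.events["visit_id"].isin(art["visit_id"]).any()


def test_ground_truth_crossings_match_threshold_replay(dataset):
    """Replaying planted vital trajectories against the catalog thresholds
    reproduces the recorded crossing days exactly (engine-independent)."""
    _, records, truth = dataset
    catalog = default_catalog()
    artifact_ids = set(truth.artifact_visits["visit_id"])
    visits = records.visits[~records.visits["visit_id"].isin(artifact_ids)].copy()
    visits["date"] = pd.to_datetime(visits["registration_datetime"]).dt.date
    enc = records.diagnoses[
        records.diagnoses["code"].str.startswith(("Z34", "O80"))
    ]["visit_id"]
    included = visits[visits["visit_id"].isin(set(enc))]

    label_of = {
        "systolic_blood_pressure": "systolic blood pressure",
        "heart_rate": "heart rate",
        "respiratory_rate": "respiratory rate",
        "oxygen_saturation": "oxygen saturation",
    }
    checked = 0
    for _, row in truth.patients.iterrows():
        if row["risk_class"] == "none" or not row["in_final_cohort"]:
            continue
        pv = included[included["person_id"] == row["person_id"]].sort_values("date")
        index_date = pv["date"].iloc[0]
        definition = catalog.by_quantity(row["risk_factor"])
        ev = records.events[
            records.events["visit_id"].isin(pv["visit_id"])
            & (records.events["event_label"] == label_of[row["risk_factor"]])
        ].merge(pv[["visit_id", "date"]], on="visit_id").sort_values("date")
        values = ev["result_value"].astype(float)
        if definition.direction == "ge":
            std_hit = values >= definition.standard_threshold
            red_hit = values >= definition.red_flag_threshold
        else:
            std_hit = values <= definition.standard_threshold
            red_hit = values <= definition.red_flag_threshold
        first_std = (ev.loc[std_hit, "date"].iloc[0] - index_date).days
        assert first_std == int(row["std_crossing_day"])
        if row["risk_class"] == "red_flag":
            first_red = (ev.loc[red_hit, "date"].iloc[0] - index_date).days
            assert first_red == int(row["rf_crossing_day"])
            assert int(row["rf_crossing_day"]) >= int(row["std_crossing_day"])
        checked += 1
    assert checked >= 10


def test_diagnosis_day_not_before_crossing(dataset):
    _, _, truth = dataset
    gt = truth.patients
    both = gt[gt["diagnosis_day"].notna() & gt["std_crossing_day"].notna()]
    assert (both["diagnosis_day"] >= both["std_crossing_day"]).all()


def test_units_are_mixed_for_weight(dataset):
    _, records, _ = dataset
    units = set(records.events.loc[records.events["event_label"] == "weight", "result_unit"])
    assert units == {"lb", "kg"}
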