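from pathlib import Path

import pandas as pd
import pytest

from matcvrisk.config import default_config
from matcvrisk.pipeline import run_all
from matcvrisk.records import RawRecordSet
from matcvrisk.synthetic_ehr import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Mid-size synthetic cohort with artifacts, shared across tests."""
    config = GeneratorConfig(n_patients=200, seed=11)
    records, truth = generate_dataset(config)
    return config, records, truth


@pytest.fixture(scope="session")
def pipeline_out(tmp_path_factory) -> Path:
    """One noise-free full-pipeline run shared by end-to-end tests."""
    out = tmp_path_factory.mktemp("pipeline")
    config = default_config()
    config["generator"]["n_patients"] = 500
    config["generator"]["vital_noise_sd"] = 0.0
    run_all(out, config, seed=20260)
    return out


def tiny_raw(
    persons=(), visits=(), events=(), diagnoses=(), family_history=()
) -> RawRecordSet:
    """Hand-built raw record set for boundary-case tests."""
    from matcvrisk.records import (
        DIAGNOSIS_COLUMNS,
        EVENT_COLUMNS,
        FAMILY_HISTORY_COLUMNS,
        PERSON_COLUMNS,
        VISIT_COLUMNS,
    )

    return RawRecordSet(
        persons=pd.DataFrame(list(persons), columns=PERSON_COLUMNS),
        visits=pd.DataFrame(list(visits), columns=VISIT_COLUMNS),
        events=pd.DataFrame(list(events), columns=EVENT_COLUMNS),
        diagnoses=pd.DataFrame(list(diagnoses), columns=DIAGNOSIS_COLUMNS),
        family_history=pd.DataFrame(list(family_history), columns=FAMILY_HISTORY_COLUMNS),
    )


def person(pid, dob="1995-03-10", name="Test Person", race="White", zipcode="90001"):
    return (pid, name, dob, race, zipcode)


def delivery_rows(pid, vid, when):
    """Visit + diagnosis rows documenting a delivery at `when` (ISO date)."""
    dt = f"{when} 10:00"
    visit = (vid, pid, dt, "hospital admission")
    dx = [
        (vid, pid, "10E0XZZ", "ICD-10-PCS", "procedure", dt),
        (vid, pid, "O80", "ICD-10-CM", "encounter", dt),
        (vid, pid, "Z37.0", "ICD-10-CM", "discharge diagnosis", dt),
    ]
    return visit, dx


def prenatal_rows(pid, vid, when, code="Z34.90"):
    dt = f"{when} 09:00"
    visit = (vid, pid, dt, "clinic appointment")
    dx = [(vid, pid, code, "ICD-10-CM", "encounter", dt)]
    return visit, dx
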