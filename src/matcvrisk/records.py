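"""In-memory containers for the raw, identifiable, visit-centric tables.

The raw model mirrors a visit-centric EHR extract: most rows tie to a
visit id, visits tie to a person id, and the clinical-events table uses a
single shared ``result_value`` field for every variable plus a
``result_unit`` field for context (lb vs kg, mm Hg, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

PERSON_COLUMNS = ["person_id", "name", "date_of_birth", "race", "zip"]
VISIT_COLUMNS = ["visit_id", "person_id", "registration_datetime", "visit_type"]
EVENT_COLUMNS = [
    "event_id",
    "visit_id",
    "person_id",
    "event_label",
    "result_value",
    "result_unit",
    "event_datetime",
]
DIAGNOSIS_COLUMNS = [
    "visit_id",
    "person_id",
    "code",
    "code_system",
    "diagnosis_type",
    "diagnosis_datetime",
]
FAMILY_HISTORY_COLUMNS = ["person_id", "item"]


class RecordIntegrityError(ValueError):
    """A table violates referential integrity (orphan visit/event rows)."""


@dataclass
class RawRecordSet:
    """Identifiable source tables before any extraction or de-identification."""

    persons: pd.DataFrame
    visits: pd.DataFrame
    events: pd.DataFrame
    diagnoses: pd.DataFrame
    family_history: pd.DataFrame

    _TABLES = {
        "persons": PERSON_COLUMNS,
        "visits": VISIT_COLUMNS,
        "events": EVENT_COLUMNS,
        "diagnoses": DIAGNOSIS_COLUMNS,
        "family_history": FAMILY_HISTORY_COLUMNS,
    }

    def validate(self) -> None:
        """Check column sets, id uniqueness and referential integrity."""
        for name, cols in self._TABLES.items():
            df = getattr(self, name)
            missing = set(cols) - set(df.columns)
            if missing:
                raise RecordIntegrityError(f"table {name} missing columns {sorted(missing)}")
        if self.persons["person_id"].duplicated().any():
            raise RecordIntegrityError("duplicate person ids")
        if self.visits["visit_id"].duplicated().any():
            raise RecordIntegrityError("duplicate visit ids")
        known_persons = set(self.persons["person_id"])
        orphan_visits = self.visits.loc[~self.visits["person_id"].isin(known_persons), "visit_id"]
        if len(orphan_visits):
            raise RecordIntegrityError(f"visits reference unknown persons: {list(orphan_visits[:5])}")
        known_visits = set(self.visits["visit_id"])
        orphan_events = self.events.loc[~self.events["visit_id"].isin(known_visits), "event_id"]
        if len(orphan_events):
            raise RecordIntegrityError(f"events reference unknown visits: {list(orphan_events[:5])}")

    def copy(self) -> "RawRecordSet":
        return RawRecordSet(
            persons=self.persons.copy(),
            visits=self.visits.copy(),
            events=self.events.copy(),
            diagnoses=self.diagnoses.copy(),
            family_history=self.family_history.copy(),
        )

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "RawRecordSet":
        directory = Path(directory)
        tables = {
            name: pd.read_csv(directory / f"{name}.csv", dtype=str, keep_default_na=False)
            for name in cls._TABLES
        }
        return cls(**tables)


@dataclass
class GroundTruth:
    """Planted truth for a synthetic cohort.

    ``patients`` carries one row per generated patient: cohort category,
    planted static risks, the planted variable-risk trajectory (factor,
    threshold-crossing days), the expected engine onsets under the risk
    rules, the planted target-condition diagnosis and its day, and the
    evaluability flag with its reason.  ``artifact_visits`` lists every
    injected nuisance visit (year-1900 historical uploads and
    communication-only visits) so filter behaviour can be verified exactly.
    All day values are calendar-day offsets from the patient's index visit
    (earliest visit surviving extraction).
    """

    patients: pd.DataFrame
    artifact_visits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["visit_id", "person_id", "artifact_type"])
    )

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(directory / "ground_truth_patients.csv", index=False)
        self.artifact_visits.to_csv(directory / "ground_truth_artifacts.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "GroundTruth":
        directory = Path(directory)
        patients = pd.read_csv(directory / "ground_truth_patients.csv")
        artifacts = pd.read_csv(
            directory / "ground_truth_artifacts.csv", dtype=str, keep_default_na=False
        )
        return cls(patients=patients, artifact_visits=artifacts)
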