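"""Category-triple assignment, unit normalization, final schema assembly.

Every record receives a three-level classification (CATEGORY,
SUB_CATEGORY, CLINICAL_CAT) so heterogeneous tables can be processed
uniformly; result values sharing the single value field are normalized to
canonical units (weights to kg); and the final relational schema is
assembled (Person, Visit, Event, Diagnosis, FamilyHX, Race) together with
a field-level data catalog.  Records matching no mapping rule are routed
to a review queue rather than dropped, mirroring the manual-review loop
any site-customized event hierarchy requires.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from matcvrisk.deidentify import DeidRecordSet

KG_PER_LB = 0.45359237

#: units already canonical; passed through unchanged
PASSTHROUGH_UNITS = {"kg", "mm Hg", "bpm", "%", "breaths/min", "kg/m2", "g/dL", "years"}


@dataclass(frozen=True)
class CategoryTriple:
    category: str
    sub_category: str = ""
    clinical_cat: str = ""

    def __post_init__(self) -> None:
        if not self.category:
            raise ValueError("category must be nonempty")


@dataclass
class MappingRule:
    """First matching rule wins; rule order is significance order."""

    table: str  # "event" or "diagnosis"
    pattern: str  # regex matched (case-insensitive, full label or type)
    triple: CategoryTriple

    def matches(self, table: str, label: str) -> bool:
        return self.table == table and re.fullmatch(self.pattern, label, re.IGNORECASE) is not None


def default_mapping_rules() -> list[MappingRule]:
    t = CategoryTriple
    return [
        MappingRule("event", r"systolic blood pressure|heart rate|respiratory rate|oxygen saturation|temperature", t("event", "measurements", "vitals")),
        MappingRule("event", r"weight|height|body mass index", t("event", "measurements", "weight and BMI")),
        MappingRule("event", r"hemoglobin|hematocrit|platelet count", t("event", "labs", "hematology")),
        MappingRule("event", r"sodium|potassium|creatinine|glucose", t("event", "labs", "metabolic panel")),
        MappingRule("event", r"dyspnea|orthopnea|tachypnea|chest pain|heart palpitations|dizziness or syncope|swelling in face or hands|new or worsening headache|asthma unresponsive to therapy", t("event", "symptoms")),
        MappingRule("event", r"loud heart murmur|basilar crackles.*", t("event", "physical findings")),
        MappingRule("event", r"prepregnancy .*|history of .*|substance use", t("event", "history")),
        MappingRule("diagnosis", r"encounter", t("diagnosis", "encounter diagnosis")),
        MappingRule("diagnosis", r"admitting( diagnosis)?", t("diagnosis", "admitting diagnosis")),
        MappingRule("diagnosis", r"discharge( diagnosis)?", t("diagnosis", "discharge diagnosis")),
        MappingRule("diagnosis", r"problem", t("diagnosis", "problem list")),
        MappingRule("diagnosis", r"procedure", t("diagnosis", "procedure")),
    ]


def load_mapping_rules(path: str | Path) -> list[MappingRule]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw["rules"]:
        triple = CategoryTriple(
            entry["category"], entry.get("sub_category", ""), entry.get("clinical_cat", "")
        )
        rules.append(MappingRule(entry["table"], entry["pattern"], triple))
    return rules


def categorize_record(
    table: str, label: str, rules: list[MappingRule]
) -> Optional[CategoryTriple]:
    """Return the triple of the first matching rule, or None (review queue)."""
    for rule in rules:
        if rule.matches(table, label.strip()):
            return rule.triple
    return None


class UnknownUnitError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedValue:
    value: Optional[float]
    unit: str
    flagged: bool = False  # unknown/missing unit: review, exclude from risk eval


def normalize_value(value: float | str, unit: str) -> NormalizedValue:
    """Canonicalize one observation value.

    Weights in lb are converted to kg (x 0.45359237, rounded to 0.01 kg);
    already-canonical units pass through; unknown units flag the record
    for review.  Blank value and unit (coded presence items) pass through
    unflagged.  Idempotent: normalizing an already-canonical value is the
    identity.
    """
    unit = str(unit).strip()
    raw = str(value).strip()
    if raw == "" and unit == "":
        return NormalizedValue(value=None, unit="", flagged=False)
    try:
        x = float(raw)
    except ValueError:
        return NormalizedValue(value=None, unit=unit, flagged=True)
    if unit == "lb":
        kg = float(
            Decimal(str(x * KG_PER_LB)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        )
        return NormalizedValue(value=kg, unit="kg", flagged=False)
    if unit in PASSTHROUGH_UNITS:
        return NormalizedValue(value=x, unit=unit, flagged=False)
    return NormalizedValue(value=x, unit=unit, flagged=True)


@dataclass
class CatalogEntry:
    table: str
    field: str
    description: str
    source: str = "pipeline"
    last_updated: str = ""


@dataclass
class HarmonizedRecordSet:
    """Final analysis schema.

    All tables except FamilyHX and Race carry both the pseudonymized
    person id and visit id; FamilyHX and Race are person-grain.
    """

    person: pd.DataFrame  # person_id, age_at_index, urbanicity
    visit: pd.DataFrame  # visit_id, person_id, day_offset, time_of_day, visit_type
    event: pd.DataFrame  # person_id, visit_id, event_label, value, unit, category, sub_category, clinical_cat, day_offset, time_of_day, needs_review
    diagnosis: pd.DataFrame  # person_id, visit_id, code, code_system, category, sub_category, clinical_cat, day_offset, time_of_day
    familyhx: pd.DataFrame  # person_id, item
    race: pd.DataFrame  # person_id, race

    _TABLES = ("person", "visit", "event", "diagnosis", "familyhx", "race")

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "HarmonizedRecordSet":
        directory = Path(directory)
        frames = {}
        for name in cls._TABLES:
            df = pd.read_csv(directory / f"{name}.csv", dtype=str, keep_default_na=False)
            for col in ("day_offset", "age_at_index"):
                if col in df.columns:
                    df[col] = df[col].astype(int)
            if "value" in df.columns:
                df["value"] = pd.to_numeric(df["value"].replace("", None), errors="coerce")
            if "needs_review" in df.columns:
                df["needs_review"] = df["needs_review"] == "True"
            frames[name] = df
        return cls(**frames)


_FIELD_DESCRIPTIONS = {
    "person_id": "pseudonymized person identifier",
    "visit_id": "pseudonymized visit identifier",
    "age_at_index": "age in completed years at the index visit",
    "urbanicity": "zip-derived urban/rural/suburban class",
    "day_offset": "calendar days from the patient's index visit",
    "time_of_day": "clock time kept for within-day sequencing",
    "visit_type": "encounter type label",
    "event_label": "source clinical-event label",
    "value": "result value in canonical units (shared field)",
    "unit": "canonical result unit",
    "category": "top-level classification (CATEGORY)",
    "sub_category": "second-level classification (SUB_CATEGORY)",
    "clinical_cat": "optional clinical classification (CLINICAL_CAT)",
    "needs_review": "unit or categorization flagged for manual review",
    "code": "diagnosis or procedure code",
    "code_system": "code system of the code field",
    "item": "family-history item",
    "race": "recorded race",
}


def build_catalog(tables: HarmonizedRecordSet) -> list[CatalogEntry]:
    """One entry per field of every emitted table (regenerated on assembly)."""
    entries = []
    for name in tables._TABLES:
        for col in getattr(tables, name).columns:
            entries.append(
                CatalogEntry(
                    table=name,
                    field=col,
                    description=_FIELD_DESCRIPTIONS.get(col, "implementation-defined field"),
                )
            )
    return entries


def catalog_to_frame(entries: list[CatalogEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.table, e.field, e.description, e.source, e.last_updated) for e in entries],
        columns=["table", "field", "description", "source", "last_updated"],
    )


class SchemaIntegrityError(ValueError):
    pass


def assemble_schema(
    deid: DeidRecordSet, rules: Optional[list[MappingRule]] = None
) -> tuple[HarmonizedRecordSet, list[CatalogEntry], pd.DataFrame]:
    """Categorize, normalize and emit the final tables plus catalog.

    Returns (tables, catalog, review_queue).  Duplicate observations
    (identical person, visit, label, value, day, time) collapse to one
    row.  Orphan events (visit absent from the visit table) raise.
    """
    rules = rules if rules is not None else default_mapping_rules()

    known_visits = set(deid.visits["visit_id"])
    orphans = deid.events.loc[~deid.events["visit_id"].isin(known_visits), "visit_id"]
    if len(orphans):
        raise SchemaIntegrityError(f"events reference unknown visits: {sorted(set(orphans))[:5]}")

    review_rows = []
    event_rows = []
    for _, row in deid.events.iterrows():
        triple = categorize_record("event", row["event_label"], rules)
        norm = normalize_value(row["result_value"], row["result_unit"])
        if triple is None:
            review_rows.append(
                ("event", row["person_id"], row["visit_id"], row["event_label"], "no mapping rule")
            )
            continue
        if norm.flagged:
            review_rows.append(
                ("event", row["person_id"], row["visit_id"], row["event_label"], "unknown unit")
            )
        event_rows.append(
            (
                row["person_id"],
                row["visit_id"],
                row["event_label"].strip().lower(),
                norm.value,
                norm.unit,
                triple.category,
                triple.sub_category,
                triple.clinical_cat,
                int(row["day_offset"]),
                row["time_of_day"],
                norm.flagged,
            )
        )
    event = pd.DataFrame(
        event_rows,
        columns=[
            "person_id",
            "visit_id",
            "event_label",
            "value",
            "unit",
            "category",
            "sub_category",
            "clinical_cat",
            "day_offset",
            "time_of_day",
            "needs_review",
        ],
    ).drop_duplicates(
        subset=["person_id", "visit_id", "event_label", "value", "day_offset", "time_of_day"]
    ).reset_index(drop=True)

    dx_rows = []
    for _, row in deid.diagnoses.iterrows():
        triple = categorize_record("diagnosis", row["diagnosis_type"], rules)
        if triple is None:
            review_rows.append(
                ("diagnosis", row["person_id"], row["visit_id"], row["diagnosis_type"], "no mapping rule")
            )
            continue
        dx_rows.append(
            (
                row["person_id"],
                row["visit_id"],
                row["code"],
                row["code_system"],
                triple.category,
                triple.sub_category,
                triple.clinical_cat,
                int(row["day_offset"]),
                row["time_of_day"],
            )
        )
    diagnosis = pd.DataFrame(
        dx_rows,
        columns=[
            "person_id",
            "visit_id",
            "code",
            "code_system",
            "category",
            "sub_category",
            "clinical_cat",
            "day_offset",
            "time_of_day",
        ],
    ).drop_duplicates().reset_index(drop=True)

    person = deid.persons[["person_id", "age_at_index", "urbanicity"]].copy()
    race = deid.persons[["person_id", "race"]].copy()
    visit = deid.visits.copy()
    familyhx = deid.family_history.copy()

    tables = HarmonizedRecordSet(
        person=person, visit=visit, event=event, diagnosis=diagnosis, familyhx=familyhx, race=race
    )
    catalog = build_catalog(tables)
    review_queue = pd.DataFrame(
        review_rows, columns=["table", "person_id", "visit_id", "label", "issue"]
    )
    return tables, catalog, review_queue
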