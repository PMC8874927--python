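"""De-identification: geographic generalization, date-to-offset transforms,
keyed pseudonymization with a local master key, and free-text stripping.

The de-identified export contains no names, zip codes, dates of birth or
calendar dates.  Zip codes are generalized to urban/rural/suburban; every
datetime is split into a clock time (kept, for within-day sequencing) and
a calendar-day offset from the patient's *index visit* — the earliest
visit surviving extraction, so that year-1900 artifacts cannot corrupt
the origin.  Person and visit ids are replaced by a salted one-way hash;
the master key mapping pseudonyms back to originals is written to a
separate, access-restricted location and never into the analysis export.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from matcvrisk.records import RawRecordSet

logger = logging.getLogger(__name__)

#: event-type labels treated as free-text/comment/date entry and stripped
DEFAULT_FREE_TEXT_LABELS = ("comment", "note", "free text", "date")

URBANICITY_CLASSES = ("urban", "rural", "suburban")


class PseudonymCollisionError(RuntimeError):
    pass


@dataclass
class MasterKey:
    """Forward/inverse pseudonym maps plus the salt that keyed them.

    Kept only in the trusted zone; the analysis export never includes it.
    The inverse map permits backtracking a pseudonym to the original id
    for revalidation.
    """

    salt: bytes
    forward: dict[str, str] = field(default_factory=dict)
    inverse: dict[str, str] = field(default_factory=dict)

    def add(self, original: str, pseudonym: str) -> None:
        if pseudonym in self.inverse and self.inverse[pseudonym] != original:
            raise PseudonymCollisionError(
                f"pseudonym collision: {original!r} and {self.inverse[pseudonym]!r} "
                f"both map to {pseudonym}"
            )
        self.forward[original] = pseudonym
        self.inverse[pseudonym] = original

    def original(self, pseudonym: str) -> str:
        return self.inverse[pseudonym]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            sorted(self.forward.items()), columns=["original_id", "pseudonym"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, salt: bytes = b"") -> "MasterKey":
        df = pd.read_csv(path, dtype=str)
        key = cls(salt=salt)
        for orig, pseu in zip(df["original_id"], df["pseudonym"]):
            key.add(orig, pseu)
        return key


def load_urbanicity_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    table = dict(zip(df["zip"], df["urbanicity"]))
    bad = set(table.values()) - set(URBANICITY_CLASSES)
    if bad:
        raise ValueError(f"urbanicity table contains unknown classes: {sorted(bad)}")
    return table


def classify_zip(zipcode: str, table: dict[str, str]) -> str:
    """Generalize a zip code to urban/rural/suburban; unknown zips log a
    warning and classify as "unknown" rather than crashing."""
    cls = table.get(str(zipcode).strip())
    if cls is None:
        logger.warning("zip code not in urbanicity table; classified unknown")
        return "unknown"
    return cls


def pseudonym(identifier: str, salt: bytes, length: int = 16) -> str:
    """Keyed one-way id transform: hex-truncated SHA-256 over salt||id."""
    return hashlib.sha256(salt + b"|" + identifier.encode()).hexdigest()[:length]


def pseudonymize_ids(
    person_ids: list[str], visit_ids: list[str], salt: bytes
) -> MasterKey:
    """Build the master key for every person and visit id.

    Distinct inputs must yield distinct pseudonyms; a collision raises,
    naming the colliding inputs.
    """
    key = MasterKey(salt=salt)
    for identifier in list(person_ids) + list(visit_ids):
        key.add(identifier, pseudonym(identifier, salt))
    return key


def strip_free_text(
    events: pd.DataFrame, free_text_labels: tuple[str, ...] = DEFAULT_FREE_TEXT_LABELS
) -> pd.DataFrame:
    """Drop events whose type/label is a free-text entry field."""
    labels = {s.lower() for s in free_text_labels}
    mask = events["event_label"].str.lower().isin(labels)
    n = int(mask.sum())
    if n:
        logger.info("stripped %d free-text events", n)
    return events.loc[~mask].reset_index(drop=True)


def _split_datetime(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    when = pd.to_datetime(series, format="%Y-%m-%d %H:%M")
    return when.dt.date, when.dt.strftime("%H:%M")


def compute_day_offsets(visit_dates: dict[str, date]) -> dict[str, int]:
    """Calendar-day offsets of one patient's visits from the index visit.

    The index visit is the earliest visit in the mapping; its offset is 0.
    Offsets of records predating the index (imported history) are negative.
    """
    if not visit_dates:
        return {}
    index_date = min(visit_dates.values())
    return {vid: (d - index_date).days for vid, d in visit_dates.items()}


@dataclass
class DeidRecordSet:
    """Analysis-export tables: pseudonymous ids, day offsets, no identifiers."""

    persons: pd.DataFrame  # person_id, age_at_index, race, urbanicity
    visits: pd.DataFrame  # visit_id, person_id, day_offset, time_of_day, visit_type
    events: pd.DataFrame  # person_id, visit_id, event_label, result_value, result_unit, day_offset, time_of_day
    diagnoses: pd.DataFrame  # person_id, visit_id, code, code_system, diagnosis_type, day_offset, time_of_day
    family_history: pd.DataFrame  # person_id, item

    _TABLES = ("persons", "visits", "events", "diagnoses", "family_history")

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "DeidRecordSet":
        directory = Path(directory)
        frames = {}
        for name in cls._TABLES:
            df = pd.read_csv(directory / f"{name}.csv", dtype=str, keep_default_na=False)
            for col in ("day_offset", "age_at_index"):
                if col in df.columns:
                    df[col] = df[col].astype(int)
            frames[name] = df
        return cls(**frames)


def _completed_years(dob: date, at: date) -> int:
    return at.year - dob.year - ((at.month, at.day) < (dob.month, dob.day))


def deidentify(
    records: RawRecordSet,
    included_visits: set[str],
    urbanicity: dict[str, str],
    salt: bytes,
    free_text_labels: tuple[str, ...] = DEFAULT_FREE_TEXT_LABELS,
) -> tuple[DeidRecordSet, MasterKey]:
    """Run all de-identification stages over the included visits.

    Returns the de-identified analysis export and the master key.  Only
    patients with at least one included visit appear in the export; dates
    of birth are replaced by age-at-index in completed years.
    """
    visits = records.visits[records.visits["visit_id"].isin(included_visits)].copy()
    vdate, vtime = _split_datetime(visits["registration_datetime"])
    visits["date"], visits["time_of_day"] = vdate, vtime

    kept_persons = sorted(set(visits["person_id"]))
    key = pseudonymize_ids(kept_persons, sorted(visits["visit_id"]), salt)

    # per-patient index visit and day offsets
    offsets: dict[str, int] = {}
    index_dates: dict[str, date] = {}
    for pid, group in visits.groupby("person_id"):
        per_visit = dict(zip(group["visit_id"], group["date"]))
        offs = compute_day_offsets(per_visit)
        offsets.update(offs)
        index_dates[pid] = min(per_visit.values())

    persons = records.persons[records.persons["person_id"].isin(kept_persons)].copy()
    persons["age_at_index"] = [
        _completed_years(date.fromisoformat(dob), index_dates[pid])
        for pid, dob in zip(persons["person_id"], persons["date_of_birth"])
    ]
    persons["urbanicity"] = [classify_zip(z, urbanicity) for z in persons["zip"]]
    persons_out = pd.DataFrame(
        {
            "person_id": persons["person_id"].map(key.forward),
            "age_at_index": persons["age_at_index"],
            "race": persons["race"],
            "urbanicity": persons["urbanicity"],
        }
    ).sort_values("person_id", kind="stable").reset_index(drop=True)

    visits_out = pd.DataFrame(
        {
            "visit_id": visits["visit_id"].map(key.forward),
            "person_id": visits["person_id"].map(key.forward),
            "day_offset": visits["visit_id"].map(offsets),
            "time_of_day": visits["time_of_day"],
            "visit_type": visits["visit_type"],
        }
    ).sort_values(["person_id", "day_offset", "time_of_day"], kind="stable").reset_index(drop=True)

    events = records.events[records.events["visit_id"].isin(included_visits)].copy()
    events = strip_free_text(events, free_text_labels)
    edate, etime = _split_datetime(events["event_datetime"])
    events_out = pd.DataFrame(
        {
            "person_id": events["person_id"].map(key.forward),
            "visit_id": events["visit_id"].map(key.forward),
            "event_label": events["event_label"],
            "result_value": events["result_value"],
            "result_unit": events["result_unit"],
            "day_offset": events["visit_id"].map(offsets),
            "time_of_day": etime,
        }
    ).reset_index(drop=True)

    dx = records.diagnoses[records.diagnoses["visit_id"].isin(included_visits)].copy()
    ddate, dtime = _split_datetime(dx["diagnosis_datetime"])
    dx_out = pd.DataFrame(
        {
            "person_id": dx["person_id"].map(key.forward),
            "visit_id": dx["visit_id"].map(key.forward),
            "code": dx["code"],
            "code_system": dx["code_system"],
            "diagnosis_type": dx["diagnosis_type"],
            "day_offset": dx["visit_id"].map(offsets),
            "time_of_day": dtime,
        }
    ).reset_index(drop=True)

    fhx = records.family_history[records.family_history["person_id"].isin(kept_persons)].copy()
    fhx_out = pd.DataFrame(
        {"person_id": fhx["person_id"].map(key.forward), "item": fhx["item"]}
    ).sort_values(["person_id", "item"], kind="stable").reset_index(drop=True)

    deid = DeidRecordSet(
        persons=persons_out,
        visits=visits_out,
        events=events_out,
        diagnoses=dx_out,
        family_history=fhx_out,
    )
    return deid, key
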