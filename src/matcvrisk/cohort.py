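"""Cohort selection, prenatal-visit identification and exclusion filters.

The study cohort is every patient with a documented delivery procedure
inside the delivery window; their prenatal encounters are found through
encounter diagnosis codes; three exclusions are then applied: visits
registered in excluded years (historical uploads register in 1900),
communication-only visits carrying no clinical events, and encounters at
which the patient was outside the 18-35 year age range.  Each exclusion
is a pure per-visit predicate, so filter order cannot change the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from matcvrisk.catalog import RiskCatalog
from matcvrisk.records import RawRecordSet
from matcvrisk.synthetic_ehr import DELIVERY_PROCEDURE_CODES


class ConfigurationError(ValueError):
    pass


class RecordValidationError(ValueError):
    """Malformed rows; carries the offending row indices."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message}: rows {rows[:10]}")
        self.rows = rows


@dataclass
class CohortCriteria:
    """Inclusion/exclusion criteria for cohort and visit selection.

    Delivery and prenatal code lists are site-configurable; the shipped
    defaults are placeholders matching the synthetic generator, not an
    authoritative clinical code set.  Ages are completed years at the
    encounter; both boundaries are inclusive.
    """

    delivery_window: tuple[date, date] = (date(2017, 1, 1), date(2020, 12, 31))
    delivery_code_list: tuple[str, ...] = DELIVERY_PROCEDURE_CODES
    prenatal_code_list: tuple[str, ...] = ("Z34", "O80")
    age_min: int = 18
    age_max: int = 35
    excluded_visit_types: tuple[str, ...] = ("portal message", "phone call")
    excluded_registration_years: tuple[int, ...] = (1900,)

    def validate(self) -> None:
        if self.age_min > self.age_max:
            raise ConfigurationError("age_min must not exceed age_max")
        if not self.delivery_window[0] < self.delivery_window[1]:
            raise ConfigurationError("delivery_window start must precede end")


@dataclass
class ExclusionReport:
    """Per-criterion tallies plus rows routed to manual review."""

    n_input: int = 0
    n_kept: int = 0
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["visit_id", "reasons"])
    )
    review: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["visit_id", "issue"])
    )

    def tally(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for reasons in self.excluded["reasons"]:
            for r in reasons.split("|"):
                counts[r] = counts.get(r, 0) + 1
        return counts


@dataclass
class ValidationReport:
    missing_variables: list[str]
    uncategorized_labels: list[str]
    sampled_visits: pd.DataFrame  # visit_id, uncategorized labels at that visit


def _parse_dates(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d %H:%M", errors="coerce")
    bad = series.index[parsed.isna() & series.notna() & (series != "")].tolist()
    if bad:
        raise RecordValidationError(f"malformed {what} datetimes", bad)
    return parsed


def select_delivery_cohort(records: RawRecordSet, criteria: CohortCriteria) -> set[str]:
    """Persons with >=1 delivery procedure dated inside the window (inclusive)."""
    criteria.validate()
    dx = records.diagnoses
    deliveries = dx[
        (dx["diagnosis_type"] == "procedure") & dx["code"].isin(criteria.delivery_code_list)
    ]
    when = _parse_dates(deliveries["diagnosis_datetime"], "delivery")
    lo, hi = criteria.delivery_window
    in_window = (when.dt.date >= lo) & (when.dt.date <= hi)
    return set(deliveries.loc[in_window, "person_id"])


def _delivery_date_by_person(records: RawRecordSet, criteria: CohortCriteria) -> pd.Series:
    dx = records.diagnoses
    deliveries = dx[
        (dx["diagnosis_type"] == "procedure") & dx["code"].isin(criteria.delivery_code_list)
    ].copy()
    deliveries["when"] = _parse_dates(deliveries["diagnosis_datetime"], "delivery")
    return deliveries.groupby("person_id")["when"].min().dt.date


def collect_prenatal_visits(
    records: RawRecordSet, cohort: set[str], criteria: CohortCriteria
) -> set[str]:
    """Visits of cohort members carrying a listed prenatal/encounter code,
    dated on or before the patient's delivery."""
    criteria.validate()
    if not criteria.prenatal_code_list:
        raise ConfigurationError("prenatal_code_list must not be empty")
    dx = records.diagnoses
    prefixes = tuple(criteria.prenatal_code_list)
    coded = dx[dx["person_id"].isin(cohort) & dx["code"].str.startswith(prefixes)]
    candidate = set(coded["visit_id"])

    visits = records.visits[records.visits["visit_id"].isin(candidate)].copy()
    visits["when"] = _parse_dates(visits["registration_datetime"], "visit").dt.date
    delivery_dates = _delivery_date_by_person(records, criteria)
    out: set[str] = set()
    for _, row in visits.iterrows():
        dd = delivery_dates.get(row["person_id"])
        if dd is not None and row["when"] <= dd:
            out.add(row["visit_id"])
    return out


def _completed_years(dob: date, at: date) -> int:
    return at.year - dob.year - ((at.month, at.day) < (dob.month, dob.day))


def apply_exclusions(
    records: RawRecordSet, visit_ids: set[str], criteria: CohortCriteria
) -> tuple[set[str], ExclusionReport]:
    """Remove excluded-year visits, eventless communication visits, and
    visits at which the patient's age falls outside [age_min, age_max].

    Visits with an unparseable/missing date of birth are routed to the
    review list (and conservatively kept), never silently dropped.
    """
    criteria.validate()
    visits = records.visits[records.visits["visit_id"].isin(visit_ids)].copy()
    visits["when"] = _parse_dates(visits["registration_datetime"], "visit")

    events_per_visit = records.events.groupby("visit_id").size()
    dob_map = records.persons.set_index("person_id")["date_of_birth"]

    report = ExclusionReport(n_input=len(visits))
    kept: set[str] = set()
    excluded_rows = []
    review_rows = []
    for _, row in visits.iterrows():
        reasons = []
        if row["when"].year in criteria.excluded_registration_years:
            reasons.append("registration_year")
        if (
            row["visit_type"] in criteria.excluded_visit_types
            and events_per_visit.get(row["visit_id"], 0) == 0
        ):
            reasons.append("communication_no_clinical_data")
        dob_raw = dob_map.get(row["person_id"], "")
        try:
            dob = date.fromisoformat(str(dob_raw))
        except ValueError:
            review_rows.append((row["visit_id"], "missing_or_malformed_dob"))
            dob = None
        if dob is not None:
            age = _completed_years(dob, row["when"].date())
            if age < criteria.age_min or age > criteria.age_max:
                reasons.append("age_out_of_range")
        if reasons:
            excluded_rows.append((row["visit_id"], "|".join(reasons)))
        else:
            kept.add(row["visit_id"])

    report.excluded = pd.DataFrame(excluded_rows, columns=["visit_id", "reasons"])
    report.review = pd.DataFrame(review_rows, columns=["visit_id", "issue"])
    report.n_kept = len(kept)
    return kept, report


def validate_extraction(
    records: RawRecordSet,
    visit_ids: set[str],
    catalog: RiskCatalog,
    sample_size: int = 5,
    seed: int = 0,
) -> ValidationReport:
    """Cross-check the events list against the risk catalog.

    Reports catalog quantities with no matching events, event labels that
    match no catalog entry (candidates for categorization review), and a
    seeded random sample of visits listing their uncategorized events for
    manual inspection.
    """
    events = records.events[records.events["visit_id"].isin(visit_ids)]
    labels = set(events["event_label"].str.lower())

    known = set(catalog.quantity_labels())
    for f in catalog:
        known.update(f.match_labels)
    # non-risk labels the pipeline still understands
    known.update({"weight", "hemoglobin", "comment", "height"})

    missing = []
    for f in catalog:
        if f.trigger == "numeric" and f.persistence == "variable":
            if not labels & set(f.match_labels):
                missing.append(f.quantity or f.id)
    uncategorized = sorted(labels - known)

    rng = np.random.default_rng(seed)
    pool = sorted(visit_ids)
    take = min(sample_size, len(pool))
    sampled = sorted(rng.choice(pool, size=take, replace=False)) if take else []
    rows = []
    for vid in sampled:
        vlabels = set(events.loc[events["visit_id"] == vid, "event_label"].str.lower())
        rows.append((vid, "|".join(sorted(vlabels - known))))
    return ValidationReport(
        missing_variables=missing,
        uncategorized_labels=uncategorized,
        sampled_visits=pd.DataFrame(rows, columns=["visit_id", "uncategorized"]),
    )


def extract(
    records: RawRecordSet, criteria: CohortCriteria | None = None
) -> tuple[set[str], set[str], ExclusionReport]:
    """Full extraction: cohort ids, included visit ids, exclusion report."""
    criteria = criteria or CohortCriteria()
    cohort = select_delivery_cohort(records, criteria)
    candidates = collect_prenatal_visits(records, cohort, criteria)
    included, report = apply_exclusions(records, candidates, criteria)
    return cohort, included, report
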