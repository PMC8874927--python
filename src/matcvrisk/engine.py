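"""Rule-based encounter-by-encounter cardiovascular risk stratification.

Each encounter is evaluated chronologically (by day offset, then clock
time) against the risk-factor catalog.  Static findings (prepregnancy
history, demographics) are active at every encounter; variable findings
must be observed at the encounter to count there (no carry-forward).  The
encounter's risk level is:

* ``red_flag``  — at least one red-flag finding (severe threshold met or
  red-flag-on-presence symptom), or four or more distinct risk factors;
* ``standard``  — at least one finding, none severe and fewer than four;
* ``none``      — no findings.

All numeric thresholds are inclusive.  A per-patient baseline mode exists
(central value of the first *k* observations per quantity, thresholds
shifted by the deviation of that baseline from the population-norm
midpoint) but is disabled by default: on retrospective extracts with
scant history it is the study-grade configuration to evaluate raw catalog
thresholds, and patients whose baselines fall outside accepted norms are
flagged and excluded from any calibration set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from matcvrisk.catalog import GE, RiskCatalog, RiskFactorDef, default_catalog
from matcvrisk.harmonize import HarmonizedRecordSet

LEVEL_NONE = "none"
LEVEL_STANDARD = "standard"
LEVEL_RED_FLAG = "red_flag"

#: distinct risk factors at/above which an encounter is red-flagged
RED_FLAG_FACTOR_COUNT = 4


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class RiskFinding:
    factor_id: str
    level: str  # standard | red_flag
    source: str = ""  # event label or item that triggered the finding
    day_offset: Optional[int] = None


@dataclass
class RiskProfile:
    person_id: str
    visit_id: str
    day_offset: int
    findings: list[RiskFinding]
    level: str

    def __post_init__(self) -> None:
        assert (self.level == LEVEL_NONE) == (not self.findings)


def evaluate_numeric(quantity: str, value: float, definition: RiskFactorDef) -> Optional[RiskFinding]:
    """Evaluate a numeric observation (canonical units) against one factor."""
    if definition.trigger != "numeric" or definition.quantity != quantity:
        raise ContractError(f"definition {definition.id} does not govern quantity {quantity!r}")
    if definition.direction == GE:
        meets_red = definition.red_flag_threshold is not None and value >= definition.red_flag_threshold
        meets_std = value >= definition.standard_threshold
    else:
        meets_red = definition.red_flag_threshold is not None and value <= definition.red_flag_threshold
        meets_std = value <= definition.standard_threshold
    if meets_red:
        return RiskFinding(definition.id, LEVEL_RED_FLAG, source=quantity)
    if meets_std:
        return RiskFinding(definition.id, LEVEL_STANDARD, source=quantity)
    return None


def evaluate_presence(label: str, catalog: RiskCatalog) -> Optional[RiskFinding]:
    """Evaluate a coded symptom/finding/history item by presence."""
    definition = catalog.by_label(label)
    if definition is None:
        return None
    level = LEVEL_RED_FLAG if definition.red_flag_on_presence else LEVEL_STANDARD
    return RiskFinding(definition.id, level, source=label.strip().lower())


def evaluate_static(
    age_at_index: Optional[int],
    race: str,
    history_labels: Iterable[str],
    bmi: Optional[float],
    catalog: RiskCatalog,
) -> list[RiskFinding]:
    """Findings from patient information that does not change over the
    pregnancy; active at every encounter."""
    findings: list[RiskFinding] = []
    for definition in catalog.static:
        if definition.trigger == "numeric":
            value = None
            if definition.quantity == "age_years":
                value = age_at_index
            elif definition.quantity == "body_mass_index":
                value = bmi
            if value is None:
                continue
            hit = evaluate_numeric(definition.quantity, float(value), definition)
            if hit is not None:
                findings.append(hit)
        else:
            if definition.id == "race_african_american":
                if str(race).strip().lower() in definition.match_labels:
                    findings.append(RiskFinding(definition.id, LEVEL_STANDARD, source="race"))
                continue
            for label in history_labels:
                if str(label).strip().lower() in definition.match_labels:
                    findings.append(RiskFinding(definition.id, LEVEL_STANDARD, source=label))
                    break
    return findings


def assess_encounter(findings: Iterable[RiskFinding]) -> tuple[str, list[RiskFinding]]:
    """Combine an encounter's findings into a risk level.

    Findings are deduplicated by factor id (a symptom coded twice, or a
    vital measured twice, counts once; the more severe level wins) before
    applying the rule: red flag on any severe finding or on >=4 distinct
    factors; standard on any finding; none otherwise.
    """
    by_id: dict[str, RiskFinding] = {}
    for f in findings:
        prev = by_id.get(f.factor_id)
        if prev is None or (prev.level == LEVEL_STANDARD and f.level == LEVEL_RED_FLAG):
            by_id[f.factor_id] = f
    deduped = list(by_id.values())
    if not deduped:
        return LEVEL_NONE, []
    if any(f.level == LEVEL_RED_FLAG for f in deduped) or len(deduped) >= RED_FLAG_FACTOR_COUNT:
        return LEVEL_RED_FLAG, deduped
    return LEVEL_STANDARD, deduped


@dataclass
class PatientBaseline:
    """Per-quantity baseline (median of first k observations) with a
    norm-conformance flag; defined only when >= k observations exist."""

    values: dict[str, float] = field(default_factory=dict)
    conforms: bool = True
    nonconforming: list[str] = field(default_factory=list)


def compute_baseline(
    observations: pd.DataFrame,  # columns: quantity, value, day_offset, time_of_day
    k: int = 3,
    norms: Optional[dict[str, tuple[float, float]]] = None,
) -> PatientBaseline:
    """Per-quantity baseline from the first *k* observations.

    Quantities with fewer than k observations get no baseline (catalog
    thresholds apply unmodified).  A baseline outside the accepted norm
    range flags the patient; flagged patients are excluded from any
    calibration/training set.
    """
    norms = norms or {}
    baseline = PatientBaseline()
    ordered = observations.sort_values(["day_offset", "time_of_day"], kind="stable")
    for quantity, group in ordered.groupby("quantity"):
        vals = group["value"].astype(float).head(k)
        if len(vals) < k:
            continue
        center = float(vals.median())
        baseline.values[quantity] = center
        if quantity in norms:
            lo, hi = norms[quantity]
            if not lo <= center <= hi:
                baseline.conforms = False
                baseline.nonconforming.append(quantity)
    return baseline


#: non-authoritative accepted ranges used when baseline mode is enabled
DEFAULT_NORMS: dict[str, tuple[float, float]] = {
    "systolic_blood_pressure": (90.0, 139.0),
    "heart_rate": (55.0, 109.0),
    "respiratory_rate": (10.0, 23.0),
    "oxygen_saturation": (97.0, 100.0),
}


def _shifted(definition: RiskFactorDef, baseline: Optional[PatientBaseline]) -> RiskFactorDef:
    """Shift numeric thresholds by (baseline - norm midpoint) when a
    baseline is defined for the quantity."""
    if baseline is None or definition.quantity not in baseline.values:
        return definition
    if definition.quantity not in DEFAULT_NORMS:
        return definition
    lo, hi = DEFAULT_NORMS[definition.quantity]
    shift = baseline.values[definition.quantity] - (lo + hi) / 2.0
    return RiskFactorDef(
        id=definition.id,
        kind=definition.kind,
        persistence=definition.persistence,
        trigger=definition.trigger,
        quantity=definition.quantity,
        direction=definition.direction,
        standard_threshold=definition.standard_threshold + shift,
        red_flag_threshold=(
            None if definition.red_flag_threshold is None else definition.red_flag_threshold + shift
        ),
        red_flag_on_presence=definition.red_flag_on_presence,
        match_labels=definition.match_labels,
    )


def run_patient(
    person_id: str,
    visits: pd.DataFrame,  # visit_id, day_offset, time_of_day
    events: pd.DataFrame,  # visit_id, event_label, value, unit, day_offset, needs_review
    static_findings: list[RiskFinding],
    catalog: RiskCatalog,
    baseline: Optional[PatientBaseline] = None,
) -> tuple[list[RiskProfile], dict[str, Optional[int]]]:
    """Evaluate one patient's encounters strictly in chronological order.

    Returns the per-encounter profiles and the onset days:
    ``onset_standard`` (first day at standard risk or higher) and
    ``onset_red_flag``.  Unordered input is sorted internally; duplicate
    (day, time) pairs keep stable input order.  Deterministic.
    """
    quantity_of = catalog.quantity_labels()
    ordered = visits.sort_values(["day_offset", "time_of_day"], kind="stable")
    profiles: list[RiskProfile] = []
    onset_standard: Optional[int] = None
    onset_red_flag: Optional[int] = None

    for _, visit in ordered.iterrows():
        day = int(visit["day_offset"])
        here = events[events["visit_id"] == visit["visit_id"]]
        findings: list[RiskFinding] = [
            RiskFinding(f.factor_id, f.level, f.source, day) for f in static_findings
        ]
        for _, ev in here.iterrows():
            if bool(ev.get("needs_review", False)):
                continue  # unresolved unit/category: not used for risk
            label = str(ev["event_label"]).strip().lower()
            if label in quantity_of and pd.notna(ev["value"]):
                definition = catalog.by_quantity(quantity_of[label])
                if definition is not None and definition.persistence == "variable":
                    hit = evaluate_numeric(
                        quantity_of[label], float(ev["value"]), _shifted(definition, baseline)
                    )
                    if hit is not None:
                        findings.append(
                            RiskFinding(hit.factor_id, hit.level, label, day)
                        )
                continue
            hit = evaluate_presence(label, catalog)
            if hit is not None and catalog.get(hit.factor_id).persistence == "variable":
                findings.append(RiskFinding(hit.factor_id, hit.level, label, day))

        level, deduped = assess_encounter(findings)
        profiles.append(
            RiskProfile(
                person_id=person_id,
                visit_id=str(visit["visit_id"]),
                day_offset=day,
                findings=deduped,
                level=level,
            )
        )
        if level in (LEVEL_STANDARD, LEVEL_RED_FLAG) and onset_standard is None:
            onset_standard = day
        if level == LEVEL_RED_FLAG and onset_red_flag is None:
            onset_red_flag = day

    return profiles, {"standard": onset_standard, "red_flag": onset_red_flag}


def extract_static_inputs(
    tables: HarmonizedRecordSet, person_id: str
) -> tuple[Optional[int], str, list[str], Optional[float]]:
    """Pull the static-risk inputs for one patient from the final schema."""
    person = tables.person[tables.person["person_id"] == person_id]
    age = int(person["age_at_index"].iloc[0]) if len(person) else None
    race_rows = tables.race[tables.race["person_id"] == person_id]
    race = str(race_rows["race"].iloc[0]) if len(race_rows) else ""
    ev = tables.event[tables.event["person_id"] == person_id]
    history = ev.loc[ev["sub_category"] == "history", "event_label"].tolist()
    bmi_rows = ev[(ev["event_label"] == "body mass index") & ev["value"].notna()].sort_values(
        ["day_offset", "time_of_day"], kind="stable"
    )
    bmi = float(bmi_rows["value"].iloc[0]) if len(bmi_rows) else None
    return age, race, history, bmi


def assess_cohort(
    tables: HarmonizedRecordSet,
    catalog: Optional[RiskCatalog] = None,
    baseline_mode: bool = False,
    baseline_k: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the engine over every patient in the harmonized set.

    Returns (profiles, onsets) as data frames.  With ``baseline_mode``
    off — the default, appropriate for retrospective extracts — catalog
    thresholds are evaluated unmodified.
    """
    catalog = catalog or default_catalog()
    quantity_of = catalog.quantity_labels()
    profile_rows = []
    onset_rows = []
    events_by_person = dict(tuple(tables.event.groupby("person_id")))
    visits_by_person = dict(tuple(tables.visit.groupby("person_id")))
    empty_events = tables.event.iloc[0:0]
    age_of = dict(zip(tables.person["person_id"], tables.person["age_at_index"]))
    race_of = dict(zip(tables.race["person_id"], tables.race["race"]))

    for person_id in tables.person["person_id"]:
        visits = visits_by_person.get(person_id)
        if visits is None or not len(visits):
            continue
        events = events_by_person.get(person_id, empty_events)
        history = events.loc[events["sub_category"] == "history", "event_label"].tolist()
        bmi_rows = events[
            (events["event_label"] == "body mass index") & events["value"].notna()
        ].sort_values(["day_offset", "time_of_day"], kind="stable")
        bmi = float(bmi_rows["value"].iloc[0]) if len(bmi_rows) else None
        static_findings = evaluate_static(
            int(age_of[person_id]), race_of.get(person_id, ""), history, bmi, catalog
        )

        baseline = None
        flagged = False
        if baseline_mode:
            obs = events[events["event_label"].isin(quantity_of) & events["value"].notna()].copy()
            obs["quantity"] = obs["event_label"].map(quantity_of)
            baseline = compute_baseline(
                obs[["quantity", "value", "day_offset", "time_of_day"]],
                k=baseline_k,
                norms=DEFAULT_NORMS,
            )
            flagged = not baseline.conforms

        profiles, onsets = run_patient(
            person_id, visits, events, static_findings, catalog, baseline=baseline
        )
        for p in profiles:
            profile_rows.append(
                (
                    p.person_id,
                    p.visit_id,
                    p.day_offset,
                    p.level,
                    len(p.findings),
                    "|".join(sorted(f.factor_id for f in p.findings)),
                )
            )
        onset_rows.append(
            (person_id, onsets["standard"], onsets["red_flag"], flagged)
        )

    profiles_df = pd.DataFrame(
        profile_rows,
        columns=["person_id", "visit_id", "day_offset", "level", "n_findings", "factor_ids"],
    )
    onsets_df = pd.DataFrame(
        onset_rows,
        columns=["person_id", "onset_standard_day", "onset_red_flag_day", "baseline_flagged"],
    )
    return profiles_df, onsets_df


# ---------------------------------------------------------------------------
# output classification with an error ledger (review-and-extend loop)


@dataclass
class ErrorLedger:
    """Accumulates labels the classification system could not explain."""

    entries: list[str] = field(default_factory=list)

    def flag(self, label: str) -> None:
        self.entries.append(label)


def default_classification_table() -> dict[str, str]:
    table = {
        "systolic blood pressure": "vital sign",
        "heart rate": "vital sign",
        "respiratory rate": "vital sign",
        "oxygen saturation": "vital sign",
        "weight": "measurement",
        "body mass index": "measurement",
        "hemoglobin": "laboratory",
    }
    for label in (
        "dyspnea",
        "orthopnea",
        "tachypnea",
        "chest pain",
        "heart palpitations",
        "dizziness or syncope",
        "swelling in face or hands",
        "new or worsening headache",
        "asthma unresponsive to therapy",
        "loud heart murmur",
        "basilar crackles in lungs",
    ):
        table[label] = "symptom or finding"
    for label in (
        "prepregnancy diagnosis of diabetes",
        "prepregnancy diagnosis of hypertension",
        "substance use",
        "history of chemotherapy",
        "history of complications in labor or delivery",
        "history of heart disease",
    ):
        table[label] = "history"
    return table


def classify_event(
    label: str, table: dict[str, str], ledger: ErrorLedger
) -> Optional[str]:
    """Classify one output label; unknown labels go to the error ledger.

    After a reviewer adds the label to the table (see
    :func:`add_classification`), re-running classification resolves all
    prior occurrences — the review-and-extend loop that, in practice,
    grows the system to cover initially unexplained classes such as organ
    failure.
    """
    key = label.strip().lower()
    if key in table:
        return table[key]
    ledger.flag(key)
    return None


def add_classification(table: dict[str, str], label: str, cls: str) -> dict[str, str]:
    table = dict(table)
    table[label.strip().lower()] = cls
    return table
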