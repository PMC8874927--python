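"""Lead time between engine risk detection and provider action.

For each patient the *delta* is the signed difference in days between the
first recorded diagnosis of a target cardiovascular condition (or a
configured intervention marker) and the engine's earliest risk onset:
``delta = reference_day - onset_day``, so a positive delta means the
engine detected risk before the provider acted.  Patients who delivered
on their first visit, or who had only one included visit, carry no
retrospective trend to evaluate and are excluded with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from matcvrisk.harmonize import HarmonizedRecordSet
from matcvrisk.synthetic_ehr import DELIVERY_PROCEDURE_CODES

#: code prefixes of the target cardiovascular conditions
DEFAULT_TARGET_CODES = ("O14", "O15", "O90.3", "I63", "I21", "I50", "I26")


@dataclass
class TargetConditionList:
    """Diagnosis-code prefixes (and optional intervention event labels)
    whose first occurrence anchors the provider-action reference day."""

    code_prefixes: tuple[str, ...] = DEFAULT_TARGET_CODES
    intervention_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.code_prefixes and not self.intervention_labels:
            raise ValueError("target condition list must not be empty")


@dataclass
class DeltaResult:
    person_id: str
    onset_day: Optional[int]
    reference_day: Optional[int]
    delta: Optional[int]
    evaluable: bool
    reason: str = ""  # delivered_first_visit | single_visit | "" when evaluable
    computable: bool = False
    not_computable_reason: str = ""


def reference_day(
    diagnoses: pd.DataFrame,
    events: pd.DataFrame,
    targets: TargetConditionList,
) -> Optional[int]:
    """Earliest day offset bearing a target diagnosis or intervention marker."""
    days = []
    if len(diagnoses):
        hit = diagnoses[diagnoses["code"].str.startswith(tuple(targets.code_prefixes))]
        if len(hit):
            days.append(int(hit["day_offset"].min()))
    if targets.intervention_labels and len(events):
        hit = events[events["event_label"].isin([s.lower() for s in targets.intervention_labels])]
        if len(hit):
            days.append(int(hit["day_offset"].min()))
    return min(days) if days else None


def compute_delta(onset: Optional[int], reference: Optional[int]) -> tuple[Optional[int], str]:
    """reference - onset in days; (None, reason) when either is undefined."""
    if onset is None and reference is None:
        return None, "no_onset_no_reference"
    if onset is None:
        return None, "no_onset"
    if reference is None:
        return None, "no_reference"
    return reference - onset, ""


def is_evaluable(
    n_visits: int, delivery_day: Optional[int], index_day: int = 0
) -> tuple[bool, str]:
    """Exclusion rules: delivery at the index visit, or a single visit,
    leave no retrospective trend to evaluate."""
    if delivery_day is not None and delivery_day == index_day:
        return False, "delivered_first_visit"
    if n_visits <= 1:
        return False, "single_visit"
    return True, ""


def evaluate_cohort(
    tables: HarmonizedRecordSet,
    onsets: pd.DataFrame,  # person_id, onset_standard_day, onset_red_flag_day
    targets: Optional[TargetConditionList] = None,
    level: str = "standard",
    delivery_codes: tuple[str, ...] = DELIVERY_PROCEDURE_CODES,
) -> list[DeltaResult]:
    """Per-patient delta results over the harmonized cohort.

    ``level="standard"`` anchors deltas at the earliest
    standard-or-higher onset (default); ``level="red_flag"`` restricts to
    red-flag onsets.
    """
    targets = targets or TargetConditionList()
    onset_col = "onset_red_flag_day" if level == "red_flag" else "onset_standard_day"
    onset_of = dict(zip(onsets["person_id"], onsets[onset_col]))

    dx_by_person = dict(tuple(tables.diagnosis.groupby("person_id")))
    ev_by_person = dict(tuple(tables.event.groupby("person_id")))
    visit_counts = tables.visit.groupby("person_id").size()
    empty_dx = tables.diagnosis.iloc[0:0]
    empty_ev = tables.event.iloc[0:0]

    results = []
    for person_id in tables.person["person_id"]:
        n_visits = int(visit_counts.get(person_id, 0))
        if n_visits == 0:
            continue
        dx = dx_by_person.get(person_id, empty_dx)
        deliveries = dx[dx["code"].isin(delivery_codes)]
        delivery_day = int(deliveries["day_offset"].min()) if len(deliveries) else None
        evaluable, reason = is_evaluable(n_visits, delivery_day)

        raw_onset = onset_of.get(person_id)
        onset = None if raw_onset is None or pd.isna(raw_onset) else int(raw_onset)
        ref = reference_day(dx, ev_by_person.get(person_id, empty_ev), targets)
        delta, why = compute_delta(onset, ref)
        results.append(
            DeltaResult(
                person_id=person_id,
                onset_day=onset,
                reference_day=ref,
                delta=delta if evaluable else None,
                evaluable=evaluable,
                reason=reason,
                computable=evaluable and delta is not None,
                not_computable_reason="" if evaluable and delta is not None else (reason or why),
            )
        )
    return results


def results_frame(results: list[DeltaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.person_id,
                r.onset_day,
                r.reference_day,
                r.delta,
                r.evaluable,
                r.reason,
                r.computable,
                r.not_computable_reason,
            )
            for r in results
        ],
        columns=[
            "person_id",
            "onset_day",
            "reference_day",
            "delta",
            "evaluable",
            "reason",
            "computable",
            "not_computable_reason",
        ],
    )


@dataclass
class DeltaSummary:
    n_patients: int = 0
    n_evaluable: int = 0
    n_delivered_first_visit: int = 0
    n_single_visit: int = 0
    n_computable: int = 0
    n_detected_earlier: int = 0  # delta > 0
    n_same_day: int = 0
    n_detected_later: int = 0  # delta < 0
    n_detected_never_diagnosed: int = 0  # onset without reference (evaluable)
    median_delta: Optional[float] = None
    q1_delta: Optional[float] = None
    q3_delta: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.__dict__.items()]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize_deltas(results: list[DeltaResult]) -> DeltaSummary:
    """Distribution summary over evaluable patients with computable deltas.

    The exclusion partition (evaluable + delivered-first-visit +
    single-visit) covers every patient exactly once.  Empty input yields
    an empty summary, not an error.
    """
    s = DeltaSummary(n_patients=len(results))
    deltas = []
    for r in results:
        if r.reason == "delivered_first_visit":
            s.n_delivered_first_visit += 1
        elif r.reason == "single_visit":
            s.n_single_visit += 1
        else:
            s.n_evaluable += 1
        if r.evaluable and r.onset_day is not None and r.reference_day is None:
            s.n_detected_never_diagnosed += 1
        if r.computable:
            deltas.append(r.delta)
    s.n_computable = len(deltas)
    if deltas:
        arr = np.asarray(deltas, dtype=float)
        s.n_detected_earlier = int((arr > 0).sum())
        s.n_same_day = int((arr == 0).sum())
        s.n_detected_later = int((arr < 0).sum())
        s.median_delta = float(np.median(arr))
        s.q1_delta = float(np.percentile(arr, 25))
        s.q3_delta = float(np.percentile(arr, 75))
    return s
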