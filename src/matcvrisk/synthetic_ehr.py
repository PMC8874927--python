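"""Synthetic visit-centric EHR generator with planted ground truth.

Real maternal EHR extracts are protected hospital records, so the pipeline
is exercised on synthetic cohorts that reproduce the *structural* features
such extracts exhibit:

* a delivery procedure documented for every patient inside a study window;
* prenatal encounters identified by encounter diagnosis codes;
* a clinical-events table sharing one result-value field across variables,
  with a unit field (weights deliberately mixed between lb and kg);
* identifiable fields (names, zip codes, full calendar dates of birth and
  of visits) that downstream de-identification must remove;
* nuisance visits: historical uploads registered in the year 1900 and
  communication-only visits (portal messages, phone calls) with no
  clinical events;
* patients who delivered on their first visit and patients with a single
  visit, which later stages must flag as non-evaluable;
* planted vital-sign risk trajectories with known threshold-crossing days
  and a planted target-condition diagnosis a known number of days later.

Values before a planted crossing are confined to bands safely below the
standard threshold and values from the crossing onward to bands at or
above it, so the crossing day is unambiguous even with nonzero
observation noise and the downstream detection lead time is recovered
exactly.  No clinically realistic physiology or inter-variable
correlation is attempted: only the statistical structure the pipeline
exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from matcvrisk.records import (
    DIAGNOSIS_COLUMNS,
    EVENT_COLUMNS,
    FAMILY_HISTORY_COLUMNS,
    PERSON_COLUMNS,
    VISIT_COLUMNS,
    GroundTruth,
    RawRecordSet,
)


class ConfigurationError(ValueError):
    """Generator configuration violates its invariants."""


#: delivery procedure codes emitted and recognized by default (placeholder
#: code set; sites configure their own list)
DELIVERY_PROCEDURE_CODES = ("10E0XZZ", "10D00Z0", "10D07Z4")

#: encounter codes marking prenatal care / delivery encounters
PRENATAL_ENCOUNTER_CODES = ("Z34.00", "Z34.80", "Z34.90")
DELIVERY_ENCOUNTER_CODE = "O80"

#: outcome-of-delivery codes -> (number of births, number of stillbirths)
PLURALITY_OUTCOMES = {
    "Z37.0": (1, 0),  # single live birth
    "Z37.1": (1, 1),  # single stillbirth
    "Z37.2": (2, 0),  # twins, both liveborn
    "Z37.51": (3, 0),  # triplets, all liveborn
}

#: target cardiovascular condition codes planted as provider diagnoses,
#: with sampling weights (hypertensive disorders dominate in practice)
TARGET_CONDITION_CODES = (
    ("O14.9", 0.75),  # preeclampsia
    ("O15.9", 0.05),  # eclampsia
    ("O90.3", 0.08),  # peripartum cardiomyopathy
    ("I63.9", 0.04),  # cerebral infarction
    ("I26.99", 0.03),  # pulmonary embolism
    ("I50.9", 0.03),  # heart failure
    ("I21.9", 0.02),  # myocardial infarction
)

_FIRST_NAMES = (
    "Ava Mia Zoe Lily Emma Nora Ruby Isla Cora Dana Elsa Faye Gia Hana Iris "
    "Jade Kira Lena Maya Nina Opal Page Quin Rosa Sara Tess Uma Vera Wren "
    "Xena Yara Zara Alma Beth Cleo Dina Edna Fern Gwen Hope"
).split()
_LAST_NAMES = (
    "Arnett Bishop Carver Dalton Ellison Foster Greaves Holt Ingram Jarvis "
    "Keller Lambert Mercer Norwood Osborne Pruitt Quimby Rourke Sutton "
    "Thatcher Underhill Vance Whitaker Xiong Yates Zimmer Ashford Barlow "
    "Crane Dunmore Easton Fairchild Garrison Hale Irwin Jessup Kirkwood "
    "Lockhart Marsh Newell"
).split()

# vitals bands: (normal_lo, normal_hi, standard_lo, standard_hi, red_lo, red_hi)
# normal bands sit clear of the standard threshold; standard bands between
# the standard and red-flag thresholds; red bands at/beyond the red-flag one
_VITAL_BANDS = {
    "systolic_blood_pressure": (100, 136, 141, 158, 161, 185),
    "heart_rate": (65, 105, 111, 118, 121, 140),
    "respiratory_rate": (14, 21, 24, 29, 30, 40),
    "oxygen_saturation": (97, 100, 95, 96, 89, 94),
}
_VITAL_LABELS = {
    "systolic_blood_pressure": ("systolic blood pressure", "mm Hg"),
    "heart_rate": ("heart rate", "bpm"),
    "respiratory_rate": ("respiratory rate", "breaths/min"),
    "oxygen_saturation": ("oxygen saturation", "%"),
}

_STATIC_EVENT_LABELS = {
    "diabetes": "prepregnancy diagnosis of diabetes",
    "hypertension": "prepregnancy diagnosis of hypertension",
    "substance_use": "substance use",
    "chemotherapy": "history of chemotherapy",
    "labor_complications": "history of complications in labor or delivery",
    "heart_disease": "history of heart disease",
}
_STATIC_FACTOR_IDS = {
    "diabetes": "prepregnancy_diabetes",
    "hypertension": "prepregnancy_hypertension",
    "substance_use": "substance_use",
    "chemotherapy": "history_chemotherapy",
    "labor_complications": "history_labor_complications",
    "heart_disease": "history_heart_disease",
}

KG_PER_LB = 0.45359237


def _default_static_prevalence() -> dict[str, float]:
    # bmi35 / african_american / substance_use taken from the reference
    # cohort structure; the remainder are modest placeholder prevalences
    return {
        "bmi35": 0.0864,
        "african_american": 0.2528,
        "substance_use": 0.107,
        "diabetes": 0.03,
        "hypertension": 0.05,
        "chemotherapy": 0.005,
        "labor_complications": 0.02,
        "heart_disease": 0.01,
    }


@dataclass
class GeneratorConfig:
    """Conditions under which a synthetic cohort is generated.

    Fractions whose reference-cohort analogue is printed in the study
    summary default to those values (delivered-on-first-visit 0.4583,
    single-visit 0.3544, red-flag 0.0529, and the static prevalences);
    the rest are the package's own defaults, documented in the methods
    note.
    """

    n_patients: int = 500
    date_window: tuple[date, date] = (date(2017, 1, 1), date(2020, 12, 31))
    frac_single_visit: float = 0.3544
    frac_delivery_first_visit: float = 0.4583
    frac_with_risk: float = 0.20
    frac_red_flag: float = 0.0529
    frac_artifact_visits: float = 0.10
    mean_visits_per_patient: float = 8.0
    lead_time_min_days: int = 7
    lead_time_max_days: int = 42
    seed: int = 0
    gestation_days: int = 280
    vital_noise_sd: float = 0.5
    frac_age_out_of_range: float = 0.06
    diagnosis_prob: float = 0.8
    comment_event_prob: float = 0.15
    symptom_at_crossing_prob: float = 0.3
    static_prevalence: dict[str, float] = field(default_factory=_default_static_prevalence)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        start, end = self.date_window
        if not start < end:
            raise ConfigurationError("date_window start must precede end")
        fracs = {
            "frac_single_visit": self.frac_single_visit,
            "frac_delivery_first_visit": self.frac_delivery_first_visit,
            "frac_with_risk": self.frac_with_risk,
            "frac_red_flag": self.frac_red_flag,
            "frac_artifact_visits": self.frac_artifact_visits,
            "frac_age_out_of_range": self.frac_age_out_of_range,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.frac_single_visit + self.frac_delivery_first_visit > 1.0:
            raise ConfigurationError(
                "frac_single_visit + frac_delivery_first_visit must not exceed 1"
            )
        if self.frac_red_flag > self.frac_with_risk:
            raise ConfigurationError("frac_red_flag cannot exceed frac_with_risk")
        if self.mean_visits_per_patient <= 0:
            raise ConfigurationError("mean_visits_per_patient must be positive")
        if not 0 <= self.lead_time_min_days <= self.lead_time_max_days:
            raise ConfigurationError("lead time bounds must satisfy 0 <= min <= max")


def urbanicity_table() -> pd.DataFrame:
    """Synthetic zip -> urban/suburban/rural lookup covering generated zips."""
    classes = ("urban", "suburban", "rural")
    rows = [(f"{90000 + i:05d}", classes[i % 3]) for i in range(60)]
    return pd.DataFrame(rows, columns=["zip", "urbanicity"])


def _fmt_dt(day: date, hhmm: str) -> str:
    return f"{day.isoformat()} {hhmm}"


def _draw_vital(rng: np.random.Generator, quantity: str, band: str, noise_sd: float) -> int:
    lo_n, hi_n, lo_s, hi_s, lo_r, hi_r = _VITAL_BANDS[quantity]
    lo, hi = {"normal": (lo_n, hi_n), "standard": (lo_s, hi_s), "red": (lo_r, hi_r)}[band]
    value = rng.uniform(lo, hi) + rng.normal(0.0, noise_sd)
    return int(np.clip(round(value), lo, hi))


def generate_cohort(config: GeneratorConfig) -> tuple[RawRecordSet, GroundTruth]:
    """Generate an identifiable raw cohort plus its planted ground truth.

    Deterministic for a fixed config (including seed).  Artifact visits are
    added separately by :func:`inject_artifacts`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    start, end = config.date_window
    span = (end - start).days

    persons, visits, events, diagnoses, famhx = [], [], [], [], []
    gt_rows = []
    visit_seq = 0
    event_seq = 0

    ztable = urbanicity_table()
    zips = ztable["zip"].tolist()

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        name = f"{rng.choice(_FIRST_NAMES)} {rng.choice(_LAST_NAMES)}"
        zipcode = str(rng.choice(zips))

        # cohort category
        u = rng.random()
        if u < config.frac_delivery_first_visit:
            category = "delivery_first"
        elif u < config.frac_delivery_first_visit + config.frac_single_visit:
            category = "single_visit"
        else:
            category = "normal"

        # age band: wholly in the 18-35 range over the pregnancy, or wholly out
        ua = rng.random()
        if ua < config.frac_age_out_of_range / 2:
            age_at_conception = int(rng.integers(14, 17))  # under-age throughout
        elif ua < config.frac_age_out_of_range:
            age_at_conception = int(rng.integers(36, 41))  # over-age throughout
        else:
            age_at_conception = int(rng.integers(18, 35))
        in_range = 18 <= age_at_conception <= 34

        delivery_date = start + timedelta(days=int(rng.integers(0, span + 1)))
        conception = delivery_date - timedelta(days=config.gestation_days)
        dob = conception - timedelta(
            days=int(round(age_at_conception * 365.25)) + int(rng.integers(30, 300))
        )

        # planted variable risk (in-range patients only; others never surface)
        ur = rng.random()
        if in_range and ur < config.frac_red_flag:
            risk_class = "red_flag"
        elif in_range and ur < config.frac_with_risk:
            risk_class = "standard"
        else:
            risk_class = "none"

        # prenatal visit days (gestational days after conception)
        if category == "normal":
            k = 2 + int(rng.poisson(max(config.mean_visits_per_patient - 3.0, 0.0)))
            k = min(k, config.gestation_days // 14)
            gest_days = sorted(
                int(d) for d in rng.choice(np.arange(30, config.gestation_days - 13), size=k, replace=False)
            )
        elif category == "single_visit":
            gest_days = [int(rng.integers(60, config.gestation_days - 29))]
        else:
            gest_days = []

        prenatal_dates = [conception + timedelta(days=d) for d in gest_days]
        # visits surviving extraction: prenatal visits, plus the delivery visit
        # unless it was recorded without an encounter code (single-visit case)
        included_dates = list(prenatal_dates)
        delivery_included = category != "single_visit"
        if delivery_included:
            included_dates.append(delivery_date)
        index_date = included_dates[0]
        offsets = [(d - index_date).days for d in included_dates]
        n_included = len(included_dates)

        # static risks
        sp = config.static_prevalence
        statics = {key: bool(rng.random() < prob) for key, prob in sp.items()}
        race = "African American" if statics["african_american"] else str(
            rng.choice(["White", "Asian", "Hispanic or Latino", "Other"])
        )
        bmi_value = (
            round(rng.uniform(35.5, 43.0), 1) if statics["bmi35"] else round(rng.uniform(19.0, 33.0), 1)
        )

        # plant trajectory placement on included visits
        factor = None
        c_idx = r_idx = None
        if risk_class != "none":
            factor = str(rng.choice(list(_VITAL_BANDS)))
            if n_included >= 3:
                c_idx = int(rng.integers(1, n_included - 1))
            elif n_included == 2:
                c_idx = 1
            else:
                c_idx = 0
            if risk_class == "red_flag":
                r_idx = min(c_idx + 1, n_included - 1)

        symptom_at_crossing = risk_class != "none" and rng.random() < config.symptom_at_crossing_prob

        # planted provider diagnosis
        dx_code = None
        dx_idx = None
        if risk_class != "none" and rng.random() < config.diagnosis_prob:
            codes, weights = zip(*TARGET_CONDITION_CODES)
            dx_code = str(rng.choice(codes, p=np.array(weights) / sum(weights)))
            lead = int(rng.integers(config.lead_time_min_days, config.lead_time_max_days + 1))
            dx_idx = n_included - 1
            for j in range(c_idx + 1, n_included):
                if offsets[j] >= offsets[c_idx] + lead:
                    dx_idx = j
                    break

        # delivery outcome (plurality)
        up = rng.random()
        if up < 0.0078:
            plurality_code = "Z37.1"
        elif up < 0.0078 + 0.0145:
            plurality_code = "Z37.2"
        elif up < 0.0078 + 0.0145 + 0.0003:
            plurality_code = "Z37.51"
        else:
            plurality_code = "Z37.0"
        n_births, n_still = PLURALITY_OUTCOMES[plurality_code]

        persons.append((pid, name, dob.isoformat(), race, zipcode))
        base_weight = rng.uniform(55.0, 90.0)
        comment_visit = (
            int(rng.integers(0, n_included)) if rng.random() < config.comment_event_prob else None
        )

        # ---- emit visits and their events ----
        all_dates = prenatal_dates + [delivery_date]
        delivery_pos = len(all_dates) - 1
        included_pos = 0  # position within included_dates
        visit_ids_by_included_pos: list[str] = []
        for pos, vdate in enumerate(all_dates):
            vid = f"V{visit_seq:06d}"
            visit_seq += 1
            hhmm = f"{int(rng.integers(7, 18)):02d}:{int(rng.integers(0, 60)):02d}"
            is_delivery = pos == delivery_pos
            vtype = "hospital admission" if is_delivery else "clinic appointment"
            visits.append((vid, pid, _fmt_dt(vdate, hhmm), vtype))

            # diagnosis rows
            if is_delivery:
                proc = str(rng.choice(DELIVERY_PROCEDURE_CODES))
                diagnoses.append((vid, pid, proc, "ICD-10-PCS", "procedure", _fmt_dt(vdate, hhmm)))
                diagnoses.append(
                    (vid, pid, plurality_code, "ICD-10-CM", "discharge diagnosis", _fmt_dt(vdate, hhmm))
                )
                if delivery_included:
                    diagnoses.append(
                        (vid, pid, DELIVERY_ENCOUNTER_CODE, "ICD-10-CM", "encounter", _fmt_dt(vdate, hhmm))
                    )
            else:
                code = str(rng.choice(PRENATAL_ENCOUNTER_CODES))
                diagnoses.append((vid, pid, code, "ICD-10-CM", "encounter", _fmt_dt(vdate, hhmm)))

            this_included = delivery_included or not is_delivery
            ipos = included_pos if this_included else None
            if this_included:
                visit_ids_by_included_pos.append(vid)

            # vitals (every clinical visit carries the four tracked vitals)
            gest_day = (vdate - conception).days
            for quantity, (label, unit) in _VITAL_LABELS.items():
                band = "normal"
                if factor == quantity and ipos is not None:
                    if risk_class == "red_flag" and ipos >= r_idx:
                        band = "red"
                    elif ipos >= c_idx:
                        band = "standard"
                value = _draw_vital(rng, quantity, band, config.vital_noise_sd)
                events.append(
                    (f"E{event_seq:07d}", vid, pid, label, str(value), unit, _fmt_dt(vdate, hhmm))
                )
                event_seq += 1

            # weight, deliberately mixed lb/kg
            wkg = base_weight + 0.03 * gest_day + rng.normal(0.0, 0.2)
            if rng.random() < 0.5:
                wval, wunit = f"{wkg / KG_PER_LB:.1f}", "lb"
            else:
                wval, wunit = f"{wkg:.1f}", "kg"
            events.append((f"E{event_seq:07d}", vid, pid, "weight", wval, wunit, _fmt_dt(vdate, hhmm)))
            event_seq += 1

            if rng.random() < 0.3:
                events.append(
                    (
                        f"E{event_seq:07d}",
                        vid,
                        pid,
                        "hemoglobin",
                        f"{rng.uniform(10.5, 14.5):.1f}",
                        "g/dL",
                        _fmt_dt(vdate, hhmm),
                    )
                )
                event_seq += 1

            # index visit carries prepregnancy BMI and coded history items
            if ipos == 0:
                events.append(
                    (
                        f"E{event_seq:07d}",
                        vid,
                        pid,
                        "body mass index",
                        f"{bmi_value:.1f}",
                        "kg/m2",
                        _fmt_dt(vdate, hhmm),
                    )
                )
                event_seq += 1
                for key, label in _STATIC_EVENT_LABELS.items():
                    if statics[key]:
                        events.append(
                            (f"E{event_seq:07d}", vid, pid, label, "", "", _fmt_dt(vdate, hhmm))
                        )
                        event_seq += 1

            if ipos is not None and ipos == c_idx and symptom_at_crossing:
                events.append(
                    (f"E{event_seq:07d}", vid, pid, "chest pain", "", "", _fmt_dt(vdate, hhmm))
                )
                event_seq += 1

            # occasional free-text comment carrying identifying text
            if ipos is not None and ipos == comment_visit:
                events.append(
                    (
                        f"E{event_seq:07d}",
                        vid,
                        pid,
                        "comment",
                        f"spoke with {name} by phone",
                        "",
                        _fmt_dt(vdate, hhmm),
                    )
                )
                event_seq += 1

            if ipos is not None and dx_idx is not None and ipos == dx_idx:
                diagnoses.append(
                    (vid, pid, dx_code, "ICD-10-CM", "discharge diagnosis", _fmt_dt(vdate, hhmm))
                )
            included_pos += 1 if this_included else 0

        # single-visit patients: provider diagnosis lands on the (excluded)
        # delivery visit, so it is invisible to the analysis extract
        if risk_class != "none" and dx_code is not None and not delivery_included:
            dx_idx = None

        if rng.random() < 0.2:
            famhx.append((pid, str(rng.choice(["family history of heart disease", "family history of diabetes", "family history of hypertension"]))))

        # ---- ground-truth oracle for expected engine onsets ----
        static_ids = set()
        if statics["bmi35"]:
            static_ids.add("prepregnancy_obesity")
        if statics["african_american"]:
            static_ids.add("race_african_american")
        for key, fid in _STATIC_FACTOR_IDS.items():
            if statics[key]:
                static_ids.add(fid)
        # completed years at index visit
        years = index_date.year - dob.year - (
            (index_date.month, index_date.day) < (dob.month, dob.day)
        )
        if years >= 40:
            static_ids.add("age_40_or_older")

        onset_std = None
        onset_rf = None
        for ipos2 in range(n_included):
            findings = set(static_ids)
            red_present = False
            if factor is not None and ipos2 >= c_idx:
                fid = {
                    "systolic_blood_pressure": "systolic_bp_high",
                    "heart_rate": "heart_rate_high",
                    "respiratory_rate": "respiratory_rate_high",
                    "oxygen_saturation": "oxygen_saturation_low",
                }[factor]
                findings.add(fid)
                if risk_class == "red_flag" and ipos2 >= r_idx:
                    red_present = True
            if symptom_at_crossing and ipos2 == c_idx:
                findings.add("chest_pain")
            if findings and onset_std is None:
                onset_std = offsets[ipos2]
            if (red_present or len(findings) >= 4) and onset_rf is None:
                onset_rf = offsets[ipos2]

        if not in_range:
            evaluable, reason = False, "age_excluded"
        elif category == "delivery_first":
            evaluable, reason = False, "delivered_first_visit"
        elif category == "single_visit":
            evaluable, reason = False, "single_visit"
        else:
            evaluable, reason = True, ""

        dx_day = offsets[dx_idx] if dx_idx is not None else None
        expected_delta = (
            dx_day - onset_std if (dx_day is not None and onset_std is not None) else None
        )

        gt_rows.append(
            {
                "person_id": pid,
                "category": category,
                "in_final_cohort": in_range,
                "age_at_index": years,
                "has_variable_risk": risk_class != "none",
                "risk_class": risk_class,
                "risk_factor": factor or "",
                "std_crossing_day": offsets[c_idx] if c_idx is not None else None,
                "rf_crossing_day": offsets[r_idx] if r_idx is not None else None,
                "onset_standard_day": onset_std,
                "onset_red_flag_day": onset_rf,
                "diagnosis_code": dx_code or "",
                "diagnosis_day": dx_day,
                "expected_delta": expected_delta,
                "delivery_day": offsets[-1] if delivery_included else None,
                "n_included_visits": n_included,
                "evaluable": evaluable,
                "evaluability_reason": reason,
                "any_risk": bool(static_ids) or risk_class != "none",
                "plurality_code": plurality_code,
                "births_recorded": n_births if delivery_included else 0,
                "stillbirths_recorded": n_still if delivery_included else 0,
                **{f"static_{k}": v for k, v in statics.items()},
            }
        )

    records = RawRecordSet(
        persons=pd.DataFrame(persons, columns=PERSON_COLUMNS),
        visits=pd.DataFrame(visits, columns=VISIT_COLUMNS),
        events=pd.DataFrame(events, columns=EVENT_COLUMNS),
        diagnoses=pd.DataFrame(diagnoses, columns=DIAGNOSIS_COLUMNS),
        family_history=pd.DataFrame(famhx, columns=FAMILY_HISTORY_COLUMNS),
    )
    truth = GroundTruth(patients=pd.DataFrame(gt_rows))
    records.validate()
    return records, truth


def inject_artifacts(
    records: RawRecordSet, config: GeneratorConfig, ground_truth: GroundTruth
) -> RawRecordSet:
    """Add year-1900 historical-upload visits and communication-only visits.

    Injected visits carry a prenatal encounter code (so they enter the
    candidate visit set like their real-world counterparts) but no clinical
    events.  Every injected visit id is recorded in
    ``ground_truth.artifact_visits`` so filter behaviour can be verified
    against an exact expectation.
    """
    config.validate()
    n_inject = int(round(config.frac_artifact_visits * len(records.visits)))
    if n_inject == 0:
        return records
    rng = np.random.default_rng([config.seed, 1])

    in_cohort = ground_truth.patients.loc[
        ground_truth.patients["in_final_cohort"], "person_id"
    ].tolist()
    if not in_cohort:
        in_cohort = ground_truth.patients["person_id"].tolist()

    visit_rows, dx_rows, art_rows = [], [], []
    next_visit = len(records.visits)
    # communication visits are dated on/before the patient's delivery so they
    # reach the exclusion filters (like their real-world counterparts) rather
    # than being dropped for falling after the delivery
    proc = records.diagnoses[records.diagnoses["diagnosis_type"] == "procedure"]
    delivery_dates = proc.groupby("person_id")["diagnosis_datetime"].min()
    for j in range(n_inject):
        pid = str(rng.choice(in_cohort))
        vid = f"V{next_visit + j:06d}"
        if j % 2 == 0:
            vtype = "historical upload"
            when = f"1900-01-{int(rng.integers(1, 29)):02d} 00:00"
        else:
            vtype = str(rng.choice(["portal message", "phone call"]))
            base = datetime.strptime(str(delivery_dates[pid]), "%Y-%m-%d %H:%M")
            when = _fmt_dt(
                (base - timedelta(days=int(rng.integers(1, 100)))).date(),
                f"{int(rng.integers(7, 18)):02d}:{int(rng.integers(0, 60)):02d}",
            )
        visit_rows.append((vid, pid, when, vtype))
        dx_rows.append((vid, pid, "Z34.90", "ICD-10-CM", "encounter", when))
        art_rows.append(
            (vid, pid, "historical_upload" if vtype == "historical upload" else "communication")
        )

    out = records.copy()
    out.visits = pd.concat(
        [out.visits, pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)], ignore_index=True
    )
    out.diagnoses = pd.concat(
        [out.diagnoses, pd.DataFrame(dx_rows, columns=DIAGNOSIS_COLUMNS)], ignore_index=True
    )
    ground_truth.artifact_visits = pd.concat(
        [
            ground_truth.artifact_visits,
            pd.DataFrame(art_rows, columns=["visit_id", "person_id", "artifact_type"]),
        ],
        ignore_index=True,
    )
    out.validate()
    return out


def generate_dataset(config: GeneratorConfig) -> tuple[RawRecordSet, GroundTruth]:
    """Convenience wrapper: generate a cohort and inject nuisance visits."""
    records, truth = generate_cohort(config)
    records = inject_artifacts(records, config, truth)
    return records, truth
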