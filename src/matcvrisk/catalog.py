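"""Registry of maternal cardiovascular risk-factor definitions.

Each factor is either *static* (does not change over the pregnancy:
demographics, prepregnancy history) or *variable* (observed at a specific
encounter: a vital-sign exceedance or a coded symptom/physical finding).
Numeric factors carry a standard threshold and, for the severe ones, a
red-flag threshold; presence factors may be red-flag on presence alone
(dyspnea, orthopnea).  All thresholds are inclusive.

The default catalog encodes the established maternal cardiovascular
risk-factor set used throughout the package:

* resting heart rate >=110 bpm (standard), >=120 bpm (red flag)
* systolic blood pressure >=140 mm Hg (standard), >=160 mm Hg (red flag)
* respiratory rate >=24 breaths/min (standard), >=30 (red flag)
* oxygen saturation <=96 % (standard), <=94 % (red flag)
* symptoms: dyspnea (red flag), orthopnea (red flag), tachypnea, asthma
  unresponsive to therapy, swelling in face or hands, new or worsening
  headache, heart palpitations, dizziness or syncope, chest pain
* physical findings: loud heart murmur, basilar crackles in lungs
* static: age >=40 years, African American race, prepregnancy obesity
  (BMI >=35), prepregnancy diabetes, prepregnancy hypertension, substance
  use, history of chemotherapy, history of complications in labor or
  delivery, history of heart disease
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

GE = "ge"
LE = "le"


@dataclass(frozen=True)
class RiskFactorDef:
    """One risk factor: how it triggers and how severe it is."""

    id: str
    kind: str  # symptom | physical_finding | history | demographic
    persistence: str  # static | variable
    trigger: str = "presence"  # presence | numeric
    quantity: Optional[str] = None  # canonical quantity label for numeric triggers
    direction: Optional[str] = None  # "ge" or "le"
    standard_threshold: Optional[float] = None
    red_flag_threshold: Optional[float] = None
    red_flag_on_presence: bool = False
    match_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.persistence not in ("static", "variable"):
            raise ValueError(f"{self.id}: persistence must be static or variable")
        if self.trigger == "numeric":
            if self.quantity is None or self.direction not in (GE, LE):
                raise ValueError(f"{self.id}: numeric trigger needs quantity and direction")
            if self.standard_threshold is None:
                raise ValueError(f"{self.id}: numeric trigger needs a standard threshold")
            if self.red_flag_threshold is not None:
                # red-flag cutoff must be at least as extreme as standard
                if self.direction == GE and self.red_flag_threshold < self.standard_threshold:
                    raise ValueError(f"{self.id}: red-flag threshold less extreme than standard")
                if self.direction == LE and self.red_flag_threshold > self.standard_threshold:
                    raise ValueError(f"{self.id}: red-flag threshold less extreme than standard")


@dataclass
class RiskCatalog:
    """Ordered collection of factor definitions with label lookups."""

    factors: list[RiskFactorDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.factors]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate factor ids in catalog")

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    def get(self, factor_id: str) -> RiskFactorDef:
        for f in self.factors:
            if f.id == factor_id:
                return f
        raise KeyError(factor_id)

    @property
    def numeric_variable(self) -> list[RiskFactorDef]:
        return [f for f in self.factors if f.trigger == "numeric" and f.persistence == "variable"]

    @property
    def static(self) -> list[RiskFactorDef]:
        return [f for f in self.factors if f.persistence == "static"]

    def by_quantity(self, quantity: str) -> Optional[RiskFactorDef]:
        for f in self.factors:
            if f.trigger == "numeric" and f.quantity == quantity:
                return f
        return None

    def by_label(self, label: str) -> Optional[RiskFactorDef]:
        """Match a coded item label to a presence factor (case-insensitive)."""
        needle = label.strip().lower()
        for f in self.factors:
            if f.trigger == "presence" and needle in f.match_labels:
                return f
        return None

    def quantity_labels(self) -> dict[str, str]:
        """event-label -> canonical quantity name, for numeric factors."""
        out: dict[str, str] = {}
        for f in self.factors:
            if f.trigger == "numeric":
                for lab in f.match_labels:
                    out[lab] = f.quantity or f.id
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RiskCatalog":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        factors = [
            RiskFactorDef(match_labels=tuple(entry.pop("match_labels", ())), **entry)
            for entry in raw["factors"]
        ]
        return cls(factors=factors)

    def to_yaml(self, path: str | Path) -> None:
        entries = []
        for f in self.factors:
            entry = {
                "id": f.id,
                "kind": f.kind,
                "persistence": f.persistence,
                "trigger": f.trigger,
                "red_flag_on_presence": f.red_flag_on_presence,
                "match_labels": list(f.match_labels),
            }
            if f.trigger == "numeric":
                entry.update(
                    quantity=f.quantity,
                    direction=f.direction,
                    standard_threshold=f.standard_threshold,
                    red_flag_threshold=f.red_flag_threshold,
                )
            entries.append(entry)
        with open(path, "w") as fh:
            yaml.safe_dump({"factors": entries}, fh, sort_keys=False)


def _presence(fid: str, kind: str, persistence: str, labels: Iterable[str], red: bool = False) -> RiskFactorDef:
    return RiskFactorDef(
        id=fid,
        kind=kind,
        persistence=persistence,
        trigger="presence",
        red_flag_on_presence=red,
        match_labels=tuple(labels),
    )


def default_catalog() -> RiskCatalog:
    """The default maternal cardiovascular risk-factor catalog."""
    factors = [
        # --- variable numeric physical findings ---
        RiskFactorDef(
            id="heart_rate_high",
            kind="physical_finding",
            persistence="variable",
            trigger="numeric",
            quantity="heart_rate",
            direction=GE,
            standard_threshold=110.0,
            red_flag_threshold=120.0,
            match_labels=("heart rate", "resting heart rate", "pulse"),
        ),
        RiskFactorDef(
            id="systolic_bp_high",
            kind="physical_finding",
            persistence="variable",
            trigger="numeric",
            quantity="systolic_blood_pressure",
            direction=GE,
            standard_threshold=140.0,
            red_flag_threshold=160.0,
            match_labels=("systolic blood pressure", "sbp"),
        ),
        RiskFactorDef(
            id="respiratory_rate_high",
            kind="physical_finding",
            persistence="variable",
            trigger="numeric",
            quantity="respiratory_rate",
            direction=GE,
            standard_threshold=24.0,
            red_flag_threshold=30.0,
            match_labels=("respiratory rate",),
        ),
        RiskFactorDef(
            id="oxygen_saturation_low",
            kind="physical_finding",
            persistence="variable",
            trigger="numeric",
            quantity="oxygen_saturation",
            direction=LE,
            standard_threshold=96.0,
            red_flag_threshold=94.0,
            match_labels=("oxygen saturation", "spo2"),
        ),
        # --- variable presence symptoms ---
        _presence("dyspnea", "symptom", "variable", ("dyspnea", "shortness of breath"), red=True),
        _presence("orthopnea", "symptom", "variable", ("orthopnea",), red=True),
        _presence("tachypnea_symptom", "symptom", "variable", ("tachypnea",)),
        _presence(
            "asthma_unresponsive",
            "symptom",
            "variable",
            ("asthma unresponsive to therapy",),
        ),
        _presence(
            "swelling_face_hands", "symptom", "variable", ("swelling in face or hands",)
        ),
        _presence(
            "new_worsening_headache",
            "symptom",
            "variable",
            ("new or worsening headache",),
        ),
        _presence("heart_palpitations", "symptom", "variable", ("heart palpitations",)),
        _presence(
            "dizziness_syncope", "symptom", "variable", ("dizziness or syncope", "syncope")
        ),
        _presence("chest_pain", "symptom", "variable", ("chest pain",)),
        # --- variable presence physical findings ---
        _presence("loud_heart_murmur", "physical_finding", "variable", ("loud heart murmur",)),
        _presence(
            "basilar_crackles",
            "physical_finding",
            "variable",
            ("basilar crackles in lungs", "basilar crackles"),
        ),
        # --- static medical history / demographics ---
        RiskFactorDef(
            id="age_40_or_older",
            kind="demographic",
            persistence="static",
            trigger="numeric",
            quantity="age_years",
            direction=GE,
            standard_threshold=40.0,
            match_labels=("age",),
        ),
        _presence(
            "race_african_american",
            "demographic",
            "static",
            ("african american", "black or african american"),
        ),
        RiskFactorDef(
            id="prepregnancy_obesity",
            kind="history",
            persistence="static",
            trigger="numeric",
            quantity="body_mass_index",
            direction=GE,
            standard_threshold=35.0,
            match_labels=("body mass index", "bmi"),
        ),
        _presence(
            "prepregnancy_diabetes",
            "history",
            "static",
            ("prepregnancy diagnosis of diabetes", "prepregnancy diabetes"),
        ),
        _presence(
            "prepregnancy_hypertension",
            "history",
            "static",
            ("prepregnancy diagnosis of hypertension", "prepregnancy hypertension"),
        ),
        _presence(
            "substance_use",
            "history",
            "static",
            ("substance use", "nicotine use", "cocaine use", "alcohol use", "methamphetamine use"),
        ),
        _presence("history_chemotherapy", "history", "static", ("history of chemotherapy",)),
        _presence(
            "history_labor_complications",
            "history",
            "static",
            ("history of complications in labor or delivery",),
        ),
        _presence(
            "history_heart_disease", "history", "static", ("history of heart disease",)
        ),
    ]
    return RiskCatalog(factors=factors)
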