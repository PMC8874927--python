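"""Cohort overview report (database-overview style summary table).

Counts are tabulated per section with an explicit denominator — patient
sections against the total patient count, birth rows against the total
birth count — and percentages are formatted by :func:`format_percentage`
(half-up to two decimals, trailing zeros trimmed), the rule that
reproduces the percentage arithmetic of published cohort overviews of
this shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd

from matcvrisk.delta import DeltaResult
from matcvrisk.harmonize import HarmonizedRecordSet
from matcvrisk.synthetic_ehr import PLURALITY_OUTCOMES

#: label -> diagnosis-code prefix; the "top detected conditions" rows are
#: derived from recorded diagnosis codes (not from engine output)
CONDITION_ROWS = (
    ("Preeclampsia", "O14"),
    ("Eclampsia", "O15"),
    ("Cardiomyopathy", "O90.3"),
    ("Cerebral infarction (stroke)", "I63"),
)

STATIC_RISK_ROWS = (
    ("BMI>=35", "prepregnancy_obesity"),
    ("African American", "race_african_american"),
    ("History of substance use", "substance_use"),
)


class UndefinedPercentageError(ZeroDivisionError):
    pass


def format_percentage(numerator: int, denominator: int) -> str:
    """100*numerator/denominator, rounded half-up to 2 decimal places,
    with trailing zeros (and a trailing decimal point) trimmed."""
    if denominator <= 0:
        raise UndefinedPercentageError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be nonnegative")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    text = str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return text.rstrip("0").rstrip(".") if "." in text else text


@dataclass
class SummaryRow:
    section: str
    label: str
    count: int
    denominator: int

    @property
    def percentage(self) -> str:
        return format_percentage(self.count, self.denominator)


@dataclass
class SummaryReport:
    rows: list[SummaryRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.section, r.label, r.count, r.denominator, r.percentage) for r in self.rows],
            columns=["section", "label", "count", "denominator", "percentage"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_text(self) -> str:
        lines = ["Database overview", "=" * 60]
        section = None
        for r in self.rows:
            if r.section != section:
                section = r.section
                lines.append(f"\n{section}")
                lines.append("-" * len(section))
            lines.append(f"  {r.label:<42s} {r.count:>9,d} ({r.percentage})")
        return "\n".join(lines) + "\n"


class StageDependencyError(RuntimeError):
    pass


def build_summary(
    tables: HarmonizedRecordSet,
    profiles: Optional[pd.DataFrame],
    delta_results: Optional[list[DeltaResult]],
) -> SummaryReport:
    """Tabulate the cohort-overview rows from completed pipeline stages."""
    for name, value in (("risk profiles", profiles), ("delta results", delta_results)):
        if value is None:
            raise StageDependencyError(f"missing upstream output: {name}")

    n_patients = len(tables.person)
    report = SummaryReport()

    at_risk = profiles.loc[profiles["level"] != "none", "person_id"].nunique()
    red_flag = profiles.loc[profiles["level"] == "red_flag", "person_id"].nunique()
    delivered_first = sum(1 for r in delta_results if r.reason == "delivered_first_visit")
    single_visit = sum(1 for r in delta_results if r.reason == "single_visit")

    pat = "Patients"
    report.rows.append(SummaryRow(pat, "Total patients in the database", n_patients, n_patients))
    report.rows.append(
        SummaryRow(pat, "Patients with at least one risk identified", at_risk, n_patients)
    )
    report.rows.append(
        SummaryRow(pat, "Patients who delivered on the first visit", delivered_first, n_patients)
    )
    report.rows.append(SummaryRow(pat, "Patients who only had 1 visit", single_visit, n_patients))
    report.rows.append(
        SummaryRow(pat, "Patients with red flag risk levels identified", red_flag, n_patients)
    )

    # births, from outcome-of-delivery codes visible in the extract
    outcome = tables.diagnosis[tables.diagnosis["code"].isin(PLURALITY_OUTCOMES)]
    outcome = outcome.drop_duplicates(subset=["person_id", "visit_id", "code"])
    counts = {code: 0 for code in PLURALITY_OUTCOMES}
    births = 0
    for code in outcome["code"]:
        n, _ = PLURALITY_OUTCOMES[code]
        births += n
        counts[code] += 1
    birth_sec = "Number of births"
    denom = max(births, 1)
    report.rows.append(SummaryRow(birth_sec, "Total births", births, denom))
    report.rows.append(
        SummaryRow(birth_sec, "Single live births", counts["Z37.0"], denom)
    )
    report.rows.append(SummaryRow(birth_sec, "Twin births", counts["Z37.2"], denom))
    report.rows.append(SummaryRow(birth_sec, "Triplet births", counts["Z37.51"], denom))
    report.rows.append(SummaryRow(birth_sec, "Stillbirths", counts["Z37.1"], denom))

    cond_sec = "Number of patients in top detected conditions (diagnosis-code-derived)"
    for label, prefix in CONDITION_ROWS:
        n = tables.diagnosis.loc[
            tables.diagnosis["code"].str.startswith(prefix), "person_id"
        ].nunique()
        report.rows.append(SummaryRow(cond_sec, label, n, n_patients))

    static_sec = "Number of patients with static risks based on category"
    for label, factor_id in STATIC_RISK_ROWS:
        n = profiles.loc[
            profiles["factor_ids"].str.contains(factor_id, regex=False), "person_id"
        ].nunique()
        report.rows.append(SummaryRow(static_sec, label, n, n_patients))

    return report
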