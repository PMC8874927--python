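"""Stage orchestration with documented CSV contracts between stages.

Every stage reads its inputs from, and writes its outputs to, fixed
locations under one output directory, so stages can be re-run
independently (from the command line or programmatically) and the whole
pipeline is reproducible byte-for-byte for a fixed seed:

    out/raw/…             identifiable synthetic source tables + urbanicity
    out/ground_truth/…    planted truth (synthetic runs only)
    out/extracted/…       included visits, exclusion + validation reports
    out/key/master_key.csv  access-restricted; never under out/deid
    out/deid/…            de-identified analysis export
    out/harmonized/…      final schema, data catalog, review queue
    out/assess/…          per-encounter risk profiles, onsets, error ledger
    out/delta/…           per-patient deltas and their summary
    out/report/…          cohort overview (CSV + human-readable text)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from matcvrisk import config as cfg
from matcvrisk.catalog import default_catalog
from matcvrisk.cohort import extract, validate_extraction
from matcvrisk.deidentify import (
    DEFAULT_FREE_TEXT_LABELS,
    DeidRecordSet,
    deidentify,
    load_urbanicity_table,
)
from matcvrisk.delta import (
    DeltaResult,
    TargetConditionList,
    evaluate_cohort,
    results_frame,
    summarize_deltas,
)
from matcvrisk.engine import (
    ErrorLedger,
    assess_cohort,
    classify_event,
    default_classification_table,
)
from matcvrisk.harmonize import HarmonizedRecordSet, assemble_schema, catalog_to_frame
from matcvrisk.records import GroundTruth, RawRecordSet
from matcvrisk.reporting import build_summary
from matcvrisk.synthetic_ehr import generate_dataset, urbanicity_table

logger = logging.getLogger(__name__)


def stage_generate(out: Path, config: dict[str, Any], seed: Optional[int] = None) -> None:
    gen_cfg = cfg.generator_config(config, seed=seed)
    records, truth = generate_dataset(gen_cfg)
    records.to_csv(out / "raw")
    urbanicity_table().to_csv(out / "raw" / "urbanicity.csv", index=False)
    truth.to_csv(out / "ground_truth")
    logger.info(
        "generate: %d persons, %d visits, %d events (%d artifact visits)",
        len(records.persons),
        len(records.visits),
        len(records.events),
        len(truth.artifact_visits),
    )


def stage_extract(out: Path, config: dict[str, Any], seed: Optional[int] = None) -> None:
    records = RawRecordSet.from_csv(out / "raw")
    criteria = cfg.cohort_criteria(config)
    cohort, included, report = extract(records, criteria)
    ex_dir = out / "extracted"
    ex_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sorted(cohort), columns=["person_id"]).to_csv(ex_dir / "cohort.csv", index=False)
    pd.DataFrame(sorted(included), columns=["visit_id"]).to_csv(
        ex_dir / "included_visits.csv", index=False
    )
    report.excluded.sort_values("visit_id", kind="stable").to_csv(
        ex_dir / "excluded_visits.csv", index=False
    )
    report.review.to_csv(ex_dir / "review_visits.csv", index=False)
    validation = validate_extraction(records, included, default_catalog(), seed=seed or 0)
    pd.DataFrame(
        {"missing_variable": validation.missing_variables}
    ).to_csv(ex_dir / "missing_variables.csv", index=False)
    pd.DataFrame({"uncategorized_label": validation.uncategorized_labels}).to_csv(
        ex_dir / "uncategorized_labels.csv", index=False
    )
    validation.sampled_visits.to_csv(ex_dir / "sampled_visits.csv", index=False)
    logger.info(
        "extract: cohort %d persons; visits in %d -> kept %d (excluded %s)",
        len(cohort),
        report.n_input,
        report.n_kept,
        report.tally(),
    )


def stage_deid(out: Path, config: dict[str, Any], seed: Optional[int] = None) -> None:
    records = RawRecordSet.from_csv(out / "raw")
    included = set(pd.read_csv(out / "extracted" / "included_visits.csv", dtype=str)["visit_id"])
    urbanicity = load_urbanicity_table(out / "raw" / "urbanicity.csv")
    deid_cfg = config.get("deid", {})
    salt = deid_cfg.get("salt")
    if salt is None:
        salt = f"pipeline-salt-{seed if seed is not None else 0}"
    free_text = tuple(deid_cfg.get("free_text_labels") or DEFAULT_FREE_TEXT_LABELS)
    deid, key = deidentify(records, included, urbanicity, str(salt).encode(), free_text)
    deid.to_csv(out / "deid")
    if deid_cfg.get("emit_master_key", True):
        # the key lives outside the analysis export directory
        key.to_csv(out / "key" / "master_key.csv")
    logger.info("deid: %d persons, %d visits exported", len(deid.persons), len(deid.visits))


def stage_harmonize(out: Path, config: dict[str, Any]) -> None:
    deid = DeidRecordSet.from_csv(out / "deid")
    tables, catalog, review = assemble_schema(deid)
    tables.to_csv(out / "harmonized")
    catalog_to_frame(catalog).to_csv(out / "harmonized" / "catalog.csv", index=False)
    review.to_csv(out / "harmonized" / "review_queue.csv", index=False)
    logger.info(
        "harmonize: %d events, %d diagnoses, %d review-queue rows",
        len(tables.event),
        len(tables.diagnosis),
        len(review),
    )


def stage_assess(out: Path, config: dict[str, Any]) -> None:
    tables = HarmonizedRecordSet.from_csv(out / "harmonized")
    assess_cfg = config.get("assess", {})
    profiles, onsets = assess_cohort(
        tables,
        baseline_mode=bool(assess_cfg.get("baseline_mode", False)),
        baseline_k=int(assess_cfg.get("baseline_k", 3)),
    )
    a_dir = out / "assess"
    a_dir.mkdir(parents=True, exist_ok=True)
    profiles.to_csv(a_dir / "profiles.csv", index=False)
    onsets.to_csv(a_dir / "onsets.csv", index=False)
    # output-classification pass with error ledger
    table = default_classification_table()
    ledger = ErrorLedger()
    rows = []
    for label in sorted(set(tables.event["event_label"])):
        rows.append((label, classify_event(label, table, ledger) or ""))
    pd.DataFrame(rows, columns=["event_label", "class"]).to_csv(
        a_dir / "classification.csv", index=False
    )
    pd.DataFrame({"unclassified_label": sorted(set(ledger.entries))}).to_csv(
        a_dir / "error_ledger.csv", index=False
    )
    logger.info(
        "assess: %d profiles (%d red flag encounters)",
        len(profiles),
        int((profiles["level"] == "red_flag").sum()),
    )


def _load_onsets(out: Path) -> pd.DataFrame:
    onsets = pd.read_csv(out / "assess" / "onsets.csv")
    for col in ("onset_standard_day", "onset_red_flag_day"):
        onsets[col] = onsets[col].astype("Int64")
        onsets[col] = onsets[col].astype(object).where(onsets[col].notna(), None)
    return onsets


def stage_delta(out: Path, config: dict[str, Any]) -> list[DeltaResult]:
    tables = HarmonizedRecordSet.from_csv(out / "harmonized")
    onsets = _load_onsets(out)
    delta_cfg = config.get("delta", {})
    prefixes = delta_cfg.get("target_code_prefixes")
    targets = TargetConditionList(
        code_prefixes=tuple(prefixes) if prefixes else TargetConditionList().code_prefixes,
        intervention_labels=tuple(delta_cfg.get("intervention_labels") or ()),
    )
    results = evaluate_cohort(tables, onsets, targets, level=delta_cfg.get("level", "standard"))
    d_dir = out / "delta"
    d_dir.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(d_dir / "deltas.csv", index=False)
    summary = summarize_deltas(results)
    summary.to_frame().to_csv(d_dir / "summary.csv", index=False)
    logger.info(
        "delta: %d evaluable / %d patients, %d computable deltas (median %s)",
        summary.n_evaluable,
        summary.n_patients,
        summary.n_computable,
        summary.median_delta,
    )
    return results


def stage_report(out: Path, config: dict[str, Any]) -> None:
    tables = HarmonizedRecordSet.from_csv(out / "harmonized")
    profiles = pd.read_csv(out / "assess" / "profiles.csv", keep_default_na=False)
    deltas = pd.read_csv(out / "delta" / "deltas.csv", keep_default_na=False)
    results = [
        DeltaResult(
            person_id=row["person_id"],
            onset_day=None if row["onset_day"] == "" else int(float(row["onset_day"])),
            reference_day=None if row["reference_day"] == "" else int(float(row["reference_day"])),
            delta=None if row["delta"] == "" else int(float(row["delta"])),
            evaluable=str(row["evaluable"]) == "True",
            reason=row["reason"],
            computable=str(row["computable"]) == "True",
            not_computable_reason=row["not_computable_reason"],
        )
        for _, row in deltas.astype(str).iterrows()
    ]
    report = build_summary(tables, profiles, results)
    r_dir = out / "report"
    r_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(r_dir / "report.csv")
    (r_dir / "report.txt").write_text(report.to_text())
    logger.info("report: %d rows written", len(report.rows))


STAGES = ("generate", "extract", "deid", "harmonize", "assess", "delta", "report")


def run_all(out: str | Path, config: dict[str, Any], seed: Optional[int] = None) -> None:
    """Run every stage in order under one output directory."""
    out = Path(out)
    stage_generate(out, config, seed)
    stage_extract(out, config, seed)
    stage_deid(out, config, seed)
    stage_harmonize(out, config)
    stage_assess(out, config)
    stage_delta(out, config)
    stage_report(out, config)


def load_ground_truth(out: str | Path) -> GroundTruth:
    return GroundTruth.from_csv(Path(out) / "ground_truth")
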