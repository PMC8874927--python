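"""YAML configuration loading for the pipeline stages.

A config file may override any subset of the defaults; unknown keys are
rejected so typos surface instead of silently using defaults.
"""

from __future__ import annotations

import copy
from datetime import date
from pathlib import Path
from typing import Any, Optional

import yaml

from matcvrisk.cohort import CohortCriteria
from matcvrisk.synthetic_ehr import GeneratorConfig


def default_config() -> dict[str, Any]:
    return {
        "generator": {},  # GeneratorConfig field overrides
        "criteria": {},  # CohortCriteria field overrides
        "deid": {
            "salt": None,  # derived from the seed when unset
            "free_text_labels": None,
            "emit_master_key": True,
        },
        "assess": {"baseline_mode": False, "baseline_k": 3},
        "delta": {
            "level": "standard",
            "target_code_prefixes": None,
            "intervention_labels": (),
        },
    }


def load_config(path: Optional[str | Path] = None) -> dict[str, Any]:
    config = default_config()
    if path is None:
        return config
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if section not in config:
            raise KeyError(f"unknown config section: {section}")
        if not isinstance(values, dict):
            raise TypeError(f"config section {section} must be a mapping")
        config[section] = {**copy.deepcopy(config[section]), **values}
    return config


def _coerce_date(value: Any) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def generator_config(config: dict[str, Any], seed: Optional[int] = None) -> GeneratorConfig:
    kwargs = dict(config.get("generator", {}))
    if "date_window" in kwargs:
        lo, hi = kwargs["date_window"]
        kwargs["date_window"] = (_coerce_date(lo), _coerce_date(hi))
    if seed is not None:
        kwargs["seed"] = seed
    cfg = GeneratorConfig(**kwargs)
    cfg.validate()
    return cfg


def cohort_criteria(config: dict[str, Any]) -> CohortCriteria:
    kwargs = dict(config.get("criteria", {}))
    if "delivery_window" in kwargs:
        lo, hi = kwargs["delivery_window"]
        kwargs["delivery_window"] = (_coerce_date(lo), _coerce_date(hi))
    for key in ("delivery_code_list", "prenatal_code_list", "excluded_visit_types"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "excluded_registration_years" in kwargs:
        kwargs["excluded_registration_years"] = tuple(
            int(y) for y in kwargs["excluded_registration_years"]
        )
    criteria = CohortCriteria(**kwargs)
    criteria.validate()
    return criteria
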