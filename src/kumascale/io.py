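"""Readers and writers for assessments and score breakdowns.

Two interchange formats are supported:

* **JSON** — a versioned document ``{"schema_version": "1.0",
  "assessments": [...]}`` whose entries mirror the
  :class:`~kumascale.model.Assessment` model.  Unknown fields are rejected
  by default and silently dropped in lenient mode.
* **long CSV** — one value per row with columns ``patient_id, visit_date,
  item_code, field, value`` (ISO 8601 dates; fixed units: mm Hg, ml, kg).
  Rows are grouped into one assessment per (patient_id, visit_date); the
  pseudo item code ``meta`` carries visit-level fields such as weight.
  The CSV form holds one finding per sensory/motor item (an optional
  ``side`` row qualifies it); per-side duplicate findings need JSON.

All schema violations in a file are collected and reported together with
row/field locations, never first-failure.
"""

from __future__ import annotations

import json
import logging
import pathlib
from typing import Iterable, Union

import pandas as pd
from pydantic import ValidationError

from .model import (
    Assessment,
    ITEM_CODES,
    MOTOR_ITEMS,
    SCHEMA_VERSION,
    ScoreBreakdown,
    SENSORY_ITEMS,
)
from .scoring_original import ScaleComparison

log = logging.getLogger("kumascale")

CSV_COLUMNS = ("patient_id", "visit_date", "item_code", "field", "value")

_SENSORY_BY_CODE = {code: (m, r) for code, m, r in SENSORY_ITEMS}
_MOTOR_BY_CODE = {code: mv for code, mv in MOTOR_ITEMS}

#: Allowed ``field`` names per CSV item code.
_CSV_FIELDS = {
    **{code: ("level", "side", "instrument") for code in _SENSORY_BY_CODE},
    **{code: ("mrc_grade", "nis_ll_grade", "side") for code in _MOTOR_BY_CODE},
    "auto_gi": ("stools_per_week", "stools_hard", "loose_stools_per_day",
                "gi_level_code"),
    "auto_orthostasis": ("sbp_supine", "sbp_standing_1min",
                         "sbp_standing_3min", "dbp_supine", "dbp_standing",
                         "supine_hypertension", "orthostatic_syncope",
                         "on_antihypertensives"),
    "auto_urination": ("residual_urine_ml", "sporadic_incontinence",
                       "catheterized", "prostate_hyperplasia_excluded"),
    "auto_dry_eyes": ("dry_eyes_grade",),
    "auto_dry_mouth": ("dry_mouth_grade", "dry_mouth_drug_induced"),
    "visc_heart": ("cardiac_level_code", "cardiac_finding_text"),
    "visc_kidney": ("dipstick_proteinuria", "proteinuria_g_per_24h",
                    "hypoalbuminemia", "oedema", "on_dialysis"),
    "meta": ("weight_kg", "height_m", "serum_albumin_g_per_L",
             "subjective_deterioration", "new_organ_involvement"),
}

_BOOL_FIELDS = {
    "stools_hard", "supine_hypertension", "orthostatic_syncope",
    "on_antihypertensives", "sporadic_incontinence", "catheterized",
    "prostate_hyperplasia_excluded", "dry_mouth_drug_induced",
    "dipstick_proteinuria", "hypoalbuminemia", "oedema", "on_dialysis",
    "subjective_deterioration", "new_organ_involvement",
}
_INT_FIELDS = {"stools_per_week", "loose_stools_per_day", "dry_eyes_grade",
               "dry_mouth_grade", "mrc_grade"}
_STR_FIELDS = {"level", "side", "instrument", "gi_level_code",
               "cardiac_level_code", "cardiac_finding_text"}


class AssessmentReadError(ValueError):
    """All schema violations found in one input file."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid input:\n" + "\n".join(errors))


def _parse_value(field: str, raw: str):
    raw = str(raw).strip()
    if field in _STR_FIELDS:
        return raw
    if field in _BOOL_FIELDS:
        low = raw.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"expected a boolean for {field}, got {raw!r}")
    if field in _INT_FIELDS:
        return int(raw)
    return float(raw)


def _strip_unknown(data: dict, model_cls) -> dict:
    known = set(model_cls.model_fields)
    dropped = [k for k in data if k not in known]
    for k in dropped:
        log.info("lenient mode: dropping unknown field %r", k)
    return {k: v for k, v in data.items() if k in known}


def _assessment_from_dict(data: dict, where: str, errors: list[str],
                          lenient: bool) -> Union[Assessment, None]:
    if lenient and isinstance(data, dict):
        data = dict(data)
        from .model import AutonomicFindings, MotorFinding, SensoryFinding, \
            VisceralFindings
        data = _strip_unknown(data, Assessment)
        if isinstance(data.get("autonomic"), dict):
            data["autonomic"] = _strip_unknown(data["autonomic"],
                                               AutonomicFindings)
        if isinstance(data.get("visceral"), dict):
            data["visceral"] = _strip_unknown(data["visceral"],
                                              VisceralFindings)
        for key, cls in (("sensory", SensoryFinding), ("motor", MotorFinding)):
            if isinstance(data.get(key), list):
                data[key] = [_strip_unknown(f, cls) if isinstance(f, dict)
                             else f for f in data[key]]
    try:
        return Assessment.model_validate(data)
    except ValidationError as exc:
        for e in exc.errors():
            loc = ".".join(str(p) for p in e["loc"])
            errors.append(f"{where}: {loc}: {e['msg']}")
        return None


def read_assessments_json(path, lenient: bool = False) -> list[Assessment]:
    doc = json.loads(pathlib.Path(path).read_text())
    errors: list[str] = []
    if isinstance(doc, dict) and "assessments" in doc:
        version = doc.get("schema_version")
        if version is not None and version != SCHEMA_VERSION:
            errors.append(f"{path}: unsupported schema_version {version!r} "
                          f"(expected {SCHEMA_VERSION!r})")
        items = doc["assessments"]
    elif isinstance(doc, list):
        items = doc
    else:
        items = [doc]
    out: list[Assessment] = []
    for i, item in enumerate(items):
        a = _assessment_from_dict(item, f"{path}: assessments[{i}]",
                                  errors, lenient)
        if a is not None:
            out.append(a)
    if errors:
        raise AssessmentReadError(errors)
    return out


def read_assessments_csv(path, lenient: bool = False) -> list[Assessment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    errors: list[str] = []
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise AssessmentReadError(
            [f"{path}: missing columns {missing_cols}; expected "
             f"{list(CSV_COLUMNS)}"])

    # line number of each row in the file (header is line 1)
    groups: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2
        code, field, value = row.item_code, row.field, row.value
        key = (row.patient_id, row.visit_date)
        if key not in groups:
            groups[key] = {"findings": {}, "meta": {}}
            order.append(key)
        if code not in _CSV_FIELDS:
            msg = f"{path}:{line}: unknown item_code {code!r}"
            if lenient:
                log.info("lenient mode: ignoring row with %s", msg)
                continue
            errors.append(msg)
            continue
        if field not in _CSV_FIELDS[code]:
            msg = (f"{path}:{line}: field {field!r} not valid for item "
                   f"{code!r} (allowed: {_CSV_FIELDS[code]})")
            if lenient:
                log.info("lenient mode: ignoring row with %s", msg)
                continue
            errors.append(msg)
            continue
        try:
            parsed = _parse_value(field, value)
        except ValueError as exc:
            errors.append(f"{path}:{line}: {exc}")
            continue
        if code == "meta":
            groups[key]["meta"][field] = parsed
        else:
            groups[key]["findings"].setdefault(code, {})[field] = parsed

    out: list[Assessment] = []
    for pid, date in order:
        bundle = groups[(pid, date)]
        data: dict = {"patient_id": pid, "visit_date": date,
                      "sensory": [], "motor": [], "autonomic": {},
                      "visceral": {}, **bundle["meta"]}
        for code, fields in bundle["findings"].items():
            if code in _SENSORY_BY_CODE:
                modality, region = _SENSORY_BY_CODE[code]
                data["sensory"].append(
                    {"modality": modality.value, "region": region.value,
                     **fields})
            elif code in _MOTOR_BY_CODE:
                data["motor"].append(
                    {"movement": _MOTOR_BY_CODE[code].value, **fields})
            elif code.startswith("auto_"):
                data["autonomic"].update(fields)
            else:
                data["visceral"].update(fields)
        a = _assessment_from_dict(data, f"{path}: ({pid}, {date})", errors,
                                  lenient=False)
        if a is not None:
            out.append(a)
    if errors:
        raise AssessmentReadError(errors)
    return out


def read_assessments(path, format: str | None = None,
                     lenient: bool = False) -> list[Assessment]:
    """Read assessments from a JSON or long-CSV file.

    ``format`` is inferred from the extension when not given.  Raises
    :class:`AssessmentReadError` carrying every violation found.
    """
    if format is None:
        format = "csv" if str(path).lower().endswith(".csv") else "json"
    if format == "json":
        return read_assessments_json(path, lenient=lenient)
    if format == "csv":
        return read_assessments_csv(path, lenient=lenient)
    raise ValueError(f"unknown format {format!r} (expected 'json' or 'csv')")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _ordered_items(item_scores: dict[str, float]) -> dict[str, float]:
    """Score-sheet item order."""
    return {code: item_scores[code] for code in ITEM_CODES
            if code in item_scores}


def breakdown_to_dict(b: ScoreBreakdown) -> dict:
    d = b.model_dump(mode="json")
    d["item_scores"] = _ordered_items(b.item_scores)
    d["complete"] = b.complete
    return d


def comparison_to_dict(c: ScaleComparison) -> dict:
    return {
        "original": breakdown_to_dict(c.original),
        "revised": breakdown_to_dict(c.revised),
        "item_deltas": _ordered_items(c.item_deltas),
        "subscore_deltas": c.subscore_deltas,
        "total_delta": c.total_delta,
    }


def write_breakdown(b: Union[ScoreBreakdown, ScaleComparison], path,
                    format: str | None = None) -> None:
    """Write a breakdown (or an original-vs-revised comparison) to JSON or
    CSV.  JSON round-trips through :func:`read_breakdown` exactly."""
    path = pathlib.Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if isinstance(b, ScaleComparison):
        payload = comparison_to_dict(b)
    else:
        payload = breakdown_to_dict(b)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    rows = []
    for name, obj in ([("original", b.original), ("revised", b.revised)]
                      if isinstance(b, ScaleComparison) else [("", b)]):
        tag = (name + "_") if name else ""
        for code, score in _ordered_items(obj.item_scores).items():
            rows.append((f"{tag}item", code, score))
        for domain, score in obj.subscores().items():
            rows.append((f"{tag}subscore", domain, score))
        rows.append((f"{tag}total", "total", obj.total))
        for code in obj.missing_items:
            rows.append((f"{tag}missing", code, ""))
    pd.DataFrame(rows, columns=["record", "code", "value"]).to_csv(
        path, index=False)


def read_breakdown(path) -> ScoreBreakdown:
    """Read back a JSON breakdown written by :func:`write_breakdown`."""
    data = json.loads(pathlib.Path(path).read_text())
    data.pop("complete", None)
    return ScoreBreakdown.model_validate(data)


def write_assessments(assessments: Iterable[Assessment], path) -> None:
    """Write assessments as a versioned JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "assessments": [a.model_dump(mode="json", exclude_none=True)
                        for a in assessments],
    }
    pathlib.Path(path).write_text(json.dumps(doc, indent=2) + "\n")
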