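"""Versioned JSON assessment report.

A report is self-contained for reproducibility: it echoes the detection
configuration, identifies every input by SHA-256 digest, embeds the
analysed schedule rows, and carries findings, the question set, answers,
confirmed factors and the measure plan as they become available along the
pipeline. Serialisation is deterministic (sorted keys, no timestamps unless
explicitly requested).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

from .detection import DetectionConfig, Finding
from .interview import Answer, ConfirmedFactorSet, QuestionInstance
from .recommender import MeasurePlan
from .schedule_io import MedicationRow, MedicationSchedule, parse_dosage_scheme

REPORT_SCHEMA_VERSION = 1


def sha256_of(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def schedule_to_json(schedule: MedicationSchedule) -> dict:
    return {
        "patient_ref": schedule.patient_ref,
        "issued_on": schedule.issued_on,
        "rows": [
            {
                "pzn": r.pzn,
                "name": r.brand_name,
                "ingredient": r.active_ingredient,
                "form": r.dosage_form,
                "strength": r.strength,
                "scheme": r.scheme_text,
                "unit": r.unit,
                "instructions": r.instructions,
                "indication": r.indication,
                "prn": r.prn,
            }
            for r in schedule.rows
        ],
    }


def schedule_from_json(doc: dict) -> MedicationSchedule:
    rows = []
    for r in doc.get("rows", []):
        scheme_text = r.get("scheme", "")
        rows.append(
            MedicationRow(
                pzn=r.get("pzn", ""),
                brand_name=r.get("name", ""),
                active_ingredient=r.get("ingredient", ""),
                dosage_form=r.get("form", ""),
                strength=r.get("strength", ""),
                scheme_text=scheme_text,
                scheme=parse_dosage_scheme(scheme_text),
                unit=r.get("unit", ""),
                instructions=r.get("instructions", ""),
                indication=r.get("indication", ""),
                prn=bool(r.get("prn", False)),
            )
        )
    return MedicationSchedule(
        rows=tuple(rows),
        patient_ref=doc.get("patient_ref", ""),
        issued_on=doc.get("issued_on", ""),
    )


def findings_to_json(findings: Sequence[Finding]) -> list[dict]:
    return [
        {
            "factor_id": f.factor_id,
            "rows": list(f.row_indices),
            "evidence": _jsonable(f.evidence.as_dict()),
            **({"device_subtype": f.device_subtype} if f.device_subtype else {}),
        }
        for f in findings
    ]


def _jsonable(value):
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def questions_to_json(question_set: Sequence[QuestionInstance]) -> list[dict]:
    return [
        {
            "instance_id": q.instance_id,
            "question_id": q.question_id,
            "kind": q.kind,
            "factor_ids": list(q.factor_ids),
            "rows": list(q.row_indices),
            "texts": list(q.texts),
            "answer_types": list(q.answer_types),
        }
        for q in question_set
    ]


def build_report(
    *,
    schedule: MedicationSchedule,
    findings: Sequence[Finding],
    config: DetectionConfig,
    warnings: Sequence[str] = (),
    question_set: Sequence[QuestionInstance] = (),
    answers: Sequence[Answer] = (),
    confirmed: Optional[ConfirmedFactorSet] = None,
    measure_plan: Optional[MeasurePlan] = None,
    input_digests: Optional[dict] = None,
    tool_version: str = "0",
    timestamp: Optional[str] = None,
) -> dict:
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": tool_version,
        "config": config.as_dict(),
        "input_digests": dict(input_digests or {}),
        "schedule": schedule_to_json(schedule),
        "findings": findings_to_json(findings),
        "warnings": list(warnings),
        "question_set": questions_to_json(question_set),
        "answers": [{"instance_id": a.instance_id, "value": _jsonable(a.value)} for a in answers],
    }
    if timestamp is not None:
        report["timestamp"] = timestamp
    if confirmed is not None:
        report["confirmed_factors"] = [
            {"factor_id": c.factor_id, "rows": list(c.row_indices), "source": c.source}
            for c in confirmed.confirmed
        ]
        report["free_text_notes"] = list(confirmed.free_text_notes)
        report["warnings"] = list(report["warnings"]) + list(confirmed.warnings)
    if measure_plan is not None:
        report["measure_plan"] = [
            {
                "factor_id": e.factor_id,
                "rows": list(e.row_indices),
                "measure_id": e.measure_id,
                "measure_type": e.measure_type,
                "payload": _jsonable(e.payload),
            }
            for e in measure_plan.entries
        ]
    return report


def dump_report(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def load_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
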