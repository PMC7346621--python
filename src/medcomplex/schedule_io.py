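"""Reading, writing and parsing of medication schedules.

The repository defines a simplified dialect of the nationally standardised
medication plan: one ``<row>`` element (or CSV line) per drug, carrying the
product identifier (PZN), brand name, active ingredient, dosage form,
strength, the raw dosage-scheme string, the dose unit, free-text
instructions, the indication, and an as-needed (PRN) flag.

The dosage scheme is the four-slot morning–noon–evening–night quadruple
(e.g. ``1-0-1-0``). :func:`parse_dosage_scheme` is total: any string that is
not 2–4 dash-separated decimal tokens degrades to an *unstructured* scheme
that keeps the original text, it never raises.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Union

from lxml import etree

logger = logging.getLogger(__name__)

#: columns of the CSV encoding, in canonical order
CSV_COLUMNS = (
    "pzn",
    "name",
    "ingredient",
    "form",
    "strength",
    "scheme",
    "unit",
    "instructions",
    "indication",
    "prn",
)
#: columns that must be present in a CSV header
MANDATORY_COLUMNS = ("pzn", "name")

_ROW_ATTRS = set(CSV_COLUMNS)


class ScheduleError(ValueError):
    """Malformed schedule input (XML/CSV parse or row-level problem)."""


@dataclass(frozen=True)
class DosageScheme:
    """Parsed dosage scheme: the four slot doses, or unstructured free text."""

    slots: Optional[tuple[float, float, float, float]] = None
    structured: bool = False

    @property
    def nonzero_slots(self) -> int:
        return sum(1 for s in self.slots if s > 0) if self.structured else 0


@dataclass(frozen=True)
class MedicationRow:
    pzn: str = ""
    brand_name: str = ""
    active_ingredient: str = ""
    dosage_form: str = ""
    strength: str = ""
    scheme_text: str = ""
    scheme: DosageScheme = field(default_factory=DosageScheme)
    unit: str = ""
    instructions: str = ""
    indication: str = ""
    prn: bool = False

    def ingredients(self) -> list[str]:
        """Individual ingredients; combination products list them '+'-separated."""
        return [p.strip().lower() for p in self.active_ingredient.split("+") if p.strip()]


@dataclass(frozen=True)
class MedicationSchedule:
    rows: tuple[MedicationRow, ...]
    patient_ref: str = ""
    issued_on: str = ""


_TOKEN_RE = re.compile(r"^(?:\d+(?:\.\d+)?|\d+/\d+)$")


def parse_dosage_scheme(text: str) -> DosageScheme:
    """Parse a raw dosage-scheme string; never raises.

    2–4 dash-separated decimal tokens become a structured scheme; 2- and
    3-token schemes are padded on the right with zero night/evening slots.
    German decimal commas are normalised to dots and fractions like ``1/2``
    are accepted. Anything else yields ``structured=False``.
    """
    if not isinstance(text, str):
        return DosageScheme()
    cleaned = text.strip().replace(",", ".")
    if not cleaned:
        return DosageScheme()
    tokens = [t.strip() for t in cleaned.split("-")]
    if not 2 <= len(tokens) <= 4:
        return DosageScheme()
    values = []
    for tok in tokens:
        if not _TOKEN_RE.match(tok):
            return DosageScheme()
        if "/" in tok:
            num, den = tok.split("/")
            if float(den) == 0:
                return DosageScheme()
            values.append(float(num) / float(den))
        else:
            values.append(float(tok))
    while len(values) < 4:
        values.append(0.0)
    return DosageScheme(slots=tuple(values), structured=True)


def normalize_pzn(pzn: str) -> str:
    """Zero-pad a PZN to 8 digits; leading zeros are significant."""
    pzn = (pzn or "").strip()
    if pzn.isdigit() and len(pzn) in (7, 8):
        return pzn.zfill(8)
    return pzn


def _build_row(values: dict[str, str], index: int) -> MedicationRow:
    pzn = normalize_pzn(values.get("pzn", ""))
    name = (values.get("name") or "").strip()
    if not pzn and not name:
        raise ScheduleError(f"row {index}: neither PZN nor brand name present")
    scheme_text = values.get("scheme", "") or ""
    prn_raw = (values.get("prn") or "").strip().lower()
    return MedicationRow(
        pzn=pzn,
        brand_name=name,
        active_ingredient=values.get("ingredient", "") or "",
        dosage_form=values.get("form", "") or "",
        strength=values.get("strength", "") or "",
        scheme_text=scheme_text,
        scheme=parse_dosage_scheme(scheme_text),
        unit=values.get("unit", "") or "",
        instructions=values.get("instructions", "") or "",
        indication=values.get("indication", "") or "",
        prn=prn_raw in ("true", "1", "yes", "x"),
    )


def read_schedule_xml(source: Union[str, Path, IO[bytes]]) -> MedicationSchedule:
    """Read the XML dialect: ``<medicationSchedule>`` with ``<row>`` children."""
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ScheduleError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "medicationSchedule":
        raise ScheduleError(f"unexpected root element {root.tag!r}")
    rows = []
    for i, el in enumerate(root.iter("row"), start=1):
        unknown = set(el.attrib) - _ROW_ATTRS
        if unknown:
            logger.warning("row %d: ignoring unknown attributes %s", i, sorted(unknown))
        rows.append(_build_row(dict(el.attrib), i))
    return MedicationSchedule(
        rows=tuple(rows),
        patient_ref=root.get("patient", ""),
        issued_on=root.get("issued", ""),
    )


def read_schedule_csv(source: Union[str, Path, IO[str]]) -> MedicationSchedule:
    """Read the CSV encoding (UTF-8, comma-separated, mandatory header)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8", newline="") as fh:
            return read_schedule_csv(fh)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise ScheduleError("no rows: empty CSV input")
    missing = [c for c in MANDATORY_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ScheduleError(f"CSV header missing mandatory column(s): {missing}")
    unknown = set(reader.fieldnames) - _ROW_ATTRS - {"patient", "issued"}
    if unknown:
        logger.warning("ignoring unknown CSV columns %s", sorted(unknown))
    rows = []
    patient_ref = issued_on = ""
    for i, record in enumerate(reader, start=1):
        patient_ref = record.get("patient") or patient_ref
        issued_on = record.get("issued") or issued_on
        rows.append(_build_row({k: (v or "") for k, v in record.items()}, i))
    if not rows:
        raise ScheduleError("no rows: CSV contains a header but no data")
    return MedicationSchedule(rows=tuple(rows), patient_ref=patient_ref, issued_on=issued_on)


def _row_values(row: MedicationRow) -> dict[str, str]:
    return {
        "pzn": row.pzn,
        "name": row.brand_name,
        "ingredient": row.active_ingredient,
        "form": row.dosage_form,
        "strength": row.strength,
        "scheme": row.scheme_text,
        "unit": row.unit,
        "instructions": row.instructions,
        "indication": row.indication,
        "prn": "true" if row.prn else "false",
    }


def write_schedule_xml(schedule: MedicationSchedule, target: Union[str, Path, IO[bytes], None] = None) -> bytes:
    root = etree.Element("medicationSchedule")
    if schedule.patient_ref:
        root.set("patient", schedule.patient_ref)
    if schedule.issued_on:
        root.set("issued", schedule.issued_on)
    for row in schedule.rows:
        etree.SubElement(root, "row", attrib=_row_values(row))
    payload = etree.tostring(root, pretty_print=True, encoding="UTF-8", xml_declaration=True)
    if target is not None:
        if isinstance(target, (str, Path)):
            Path(target).write_bytes(payload)
        else:
            target.write(payload)
    return payload


def write_schedule_csv(schedule: MedicationSchedule, target: Union[str, Path, IO[str], None] = None) -> str:
    buf = io.StringIO()
    columns = list(CSV_COLUMNS) + ["patient", "issued"]
    writer = csv.DictWriter(buf, fieldnames=columns, lineterminator="\n")
    writer.writeheader()
    for i, row in enumerate(schedule.rows):
        values = _row_values(row)
        values["patient"] = schedule.patient_ref if i == 0 else ""
        values["issued"] = schedule.issued_on if i == 0 else ""
        writer.writerow(values)
    payload = buf.getvalue()
    if target is not None:
        if isinstance(target, (str, Path)):
            Path(target).write_text(payload, encoding="utf-8")
        else:
            target.write(payload)
    return payload
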