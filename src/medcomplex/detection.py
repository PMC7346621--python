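"""Automated detection of complexity factors in a medication schedule.

Implements the 38 automated rules over four mechanism families:

* **PZN rules** — the row's product identifier is looked up in the drug
  reference and product attributes (form class, device subtype,
  palatability, training requirement, self-measurement linkage,
  prescription-only status) drive the dosage-form, product and process
  factors.
* **Dosage-scheme rules** — seven rules over the parsed four-slot scheme
  (splitting, >2× daily, noon dose, doses ≥ 2 units, differing doses,
  variable dosing, a drug alone at a time point).
* **Schedule-level rules** — the polypharmacy line count and duplicated
  active ingredients across rows.
* **Keyword rules** — case-insensitive word-boundary matching of per-factor
  phrase lists against the free-text instructions (and, for frequency-style
  factors, the raw scheme text).

Findings carry machine-checkable evidence (matched phrase and span, slot
pattern, product attribute, line count, or ingredient pair) so a report can
show *why* a factor fired. Detection is a pure function of its inputs: the
same schedule, reference, catalogue, lexicon and configuration always yield
the identical finding list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .drug_reference import DrugRecord, DrugReference
from .knowledge_base import KnowledgeBase
from .schedule_io import MedicationRow, MedicationSchedule

# factors whose dosage-form class alone triggers them
FORM_CLASS_FACTORS = {
    "inhaler": "inhalers",
    "transdermal_patch": "transdermal_patches",
    "nasal": "nasal_rx",
    "oropharyngeal_solid": "oropharyngeal_solid",
    "oropharyngeal_liquid": "oropharyngeal_liquid",
    "ophthalmic": "ophthalmic",
    "rectal": "rectal",
    "dermatological": "dermatological_rx",
    "liquid_oral": "liquid_oral",
    "otological": "otological",
    "vaginal": "vaginal",
}
# form factors gated on prescription-only status
RX_ONLY_FORM_FACTORS = ("nasal_rx", "dermatological_rx")


class LexiconError(ValueError):
    pass


@dataclass(frozen=True)
class LexiconEntry:
    phrases: tuple[str, ...]
    provenance: str = "repo-default"
    scan_scheme_text: bool = False


@dataclass(frozen=True)
class KeywordLexicon:
    """Per-factor keyword phrase lists; word-boundary, case-insensitive."""

    language: str
    entries: dict[str, LexiconEntry]


@dataclass(frozen=True)
class Evidence:
    """Enum-tagged payload explaining why a finding fired.

    ``kind`` is one of ``matched_keyword``, ``slot_pattern``,
    ``pzn_attribute``, ``pzn_keyword``, ``line_count``, ``ingredient_pair``.
    """

    kind: str
    detail: tuple[tuple[str, object], ...]

    @staticmethod
    def make(kind: str, **detail) -> "Evidence":
        return Evidence(kind=kind, detail=tuple(sorted(detail.items())))

    def as_dict(self) -> dict:
        return {"kind": self.kind, **{k: v for k, v in self.detail}}


@dataclass(frozen=True)
class Finding:
    factor_id: str
    row_indices: tuple[int, ...]
    evidence: Evidence
    device_subtype: Optional[str] = None


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables of the detection run; echoed into every report.

    ``polypharmacy_threshold`` is the schedule line count at which the
    total-number-of-drugs factor fires. The plan format itself sets no
    cut-off; the default of 5 follows the common polypharmacy convention
    and is freely configurable.
    """

    polypharmacy_threshold: int = 5
    language: str = "en"
    missing_pzn_is_error: bool = False

    def as_dict(self) -> dict:
        return {
            "polypharmacy_threshold": self.polypharmacy_threshold,
            "language": self.language,
            "missing_pzn_is_error": self.missing_pzn_is_error,
        }


def default_lexicon_path(language: str = "en") -> Path:
    return Path(str(resources.files("medcomplex").joinpath(f"data/lexicon_{language}.yaml")))


def load_lexicon(path: Union[str, Path, None] = None, language: str = "en") -> KeywordLexicon:
    lex_path = Path(path) if path is not None else default_lexicon_path(language)
    doc = yaml.safe_load(lex_path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "factors" not in doc:
        raise LexiconError(f"{lex_path}: expected a mapping with a 'factors' key")
    entries = {}
    for fid, raw in (doc["factors"] or {}).items():
        phrases = tuple(str(p) for p in raw.get("phrases") or ())
        if not phrases:
            raise LexiconError(f"{lex_path}: factor {fid!r} has an empty phrase list")
        entries[fid] = LexiconEntry(
            phrases=phrases,
            provenance=raw.get("provenance", "repo-default"),
            scan_scheme_text=bool(raw.get("scan_scheme_text", False)),
        )
    return KeywordLexicon(language=doc.get("language", language), entries=entries)


def validate_lexicon(lexicon: KeywordLexicon, kb: KnowledgeBase) -> list[str]:
    """Every keyword-mechanism factor must have a non-empty phrase list."""
    violations = []
    for f in kb.factors:
        if f.mechanism in ("keywords", "pzn_and_keywords"):
            entry = lexicon.entries.get(f.factor_id)
            if entry is None or not entry.phrases:
                violations.append(f"lexicon: no phrases for keyword factor {f.factor_id!r}")
    return violations


def _phrase_regex(phrase: str) -> re.Pattern:
    # word-boundary on both sides; internal whitespace matches any single run
    escaped = r"\s+".join(re.escape(tok) for tok in phrase.split())
    return re.compile(rf"(?<!\w){escaped}(?!\w)", re.IGNORECASE | re.UNICODE)


def match_keywords(text: str, phrases: tuple[str, ...]) -> list[tuple[str, tuple[int, int]]]:
    """All word-boundary hits of ``phrases`` in ``text`` with their spans."""
    if not text:
        return []
    hits = []
    for phrase in phrases:
        for m in _phrase_regex(phrase).finditer(text):
            hits.append((phrase, (m.start(), m.end())))
    hits.sort(key=lambda h: (h[1][0], h[0]))
    return hits


# ---------------------------------------------------------------------------
# rule families
# ---------------------------------------------------------------------------


def apply_pzn_rules(
    row_index: int,
    row: MedicationRow,
    record: DrugRecord,
    kb: KnowledgeBase,
    lexicon: KeywordLexicon,
) -> list[Finding]:
    """Product-attribute rules for one row with a resolved drug record."""
    findings = []
    factor_id = None
    if record.form_class == "injection":
        factor_id = (
            "injection_prefilled"
            if record.device_subtype == "prefilled_injector"
            else "injection_non_prefilled"
        )
    else:
        factor_id = FORM_CLASS_FACTORS.get(record.form_class)
    if factor_id in RX_ONLY_FORM_FACTORS and not record.prescription_only:
        factor_id = None
    if factor_id is not None:
        findings.append(
            Finding(
                factor_id=factor_id,
                row_indices=(row_index,),
                evidence=Evidence.make(
                    "pzn_attribute",
                    attribute="form_class",
                    value=record.form_class,
                    pzn=record.pzn,
                ),
                device_subtype=record.device_subtype,
            )
        )
    if record.palatability_issue and record.form_class == "liquid_oral":
        findings.append(
            Finding(
                factor_id="unfriendly_liquid_oral",
                row_indices=(row_index,),
                evidence=Evidence.make(
                    "pzn_attribute", attribute="palatability_issue", value=True, pzn=record.pzn
                ),
            )
        )
    if record.requires_technique_training:
        findings.append(
            Finding(
                factor_id="lack_of_training",
                row_indices=(row_index,),
                evidence=Evidence.make(
                    "pzn_attribute",
                    attribute="requires_technique_training",
                    value=True,
                    pzn=record.pzn,
                ),
            )
        )
    if record.self_measurement_linked:
        entry = lexicon.entries.get("complex_measurements")
        hits = match_keywords(row.instructions, entry.phrases) if entry else []
        if hits:
            findings.append(
                Finding(
                    factor_id="complex_measurements",
                    row_indices=(row_index,),
                    evidence=Evidence.make(
                        "pzn_keyword",
                        attribute="self_measurement_linked",
                        pzn=record.pzn,
                        matches=tuple(h[0] for h in hits),
                    ),
                )
            )
    return findings


def _is_solid_oral(row: MedicationRow, record: Optional[DrugRecord]) -> bool:
    if record is not None:
        return record.form_class == "solid_oral"
    form = row.dosage_form.lower()
    return any(tok in form for tok in ("tabl", "capsule", "kapsel", "dragee"))


def _slot_matrix(schedule: MedicationSchedule) -> list[Optional[tuple[float, ...]]]:
    return [r.scheme.slots if r.scheme.structured else None for r in schedule.rows]


def apply_scheme_rules(
    row_index: int,
    row: MedicationRow,
    record: Optional[DrugRecord],
    schedule: MedicationSchedule,
    kb: KnowledgeBase,
) -> list[Finding]:
    """The seven dosage-scheme rules for one row.

    The lone-drug-at-a-time-point rule is evaluated against the whole
    schedule and only when at least two rows carry structured schemes — a
    single-drug plan trivially occupies its slots alone and is not flagged.
    """
    findings = []

    def add(factor_id: str, **detail) -> None:
        findings.append(
            Finding(
                factor_id=factor_id,
                row_indices=(row_index,),
                evidence=Evidence.make("slot_pattern", **detail),
            )
        )

    scheme = row.scheme
    if scheme.structured:
        slots = scheme.slots
        if _is_solid_oral(row, record) and any(s > 0 and s != int(s) for s in slots):
            add("tablet_splitting", slots=slots, rule="fractional_dose")
        if sum(1 for s in slots if s > 0) > 2:
            add("more_than_twice_daily", slots=slots, rule="nonzero_slots_gt_2")
        if slots[1] > 0:
            add("lunch_time", slots=slots, rule="noon_slot")
        if any(s >= 2 for s in slots):
            add("multiple_doses_concurrently", slots=slots, rule="slot_dose_ge_2")
        if len({s for s in slots if s > 0}) >= 2:
            add("different_doses_same_day", slots=slots, rule="distinct_nonzero_doses")
        matrix = _slot_matrix(schedule)
        structured_rows = [i for i, m in enumerate(matrix) if m is not None]
        if len(structured_rows) >= 2:
            for j in range(4):
                if slots[j] > 0 and all(
                    matrix[i] is None or matrix[i][j] == 0
                    for i in range(len(matrix))
                    if i != row_index
                ):
                    add("single_drug_at_timepoint", slots=slots, rule="isolated_slot", slot=j)
                    break
    else:
        if row.scheme_text.strip() and not row.prn:
            add("variable_dosing", slots=None, rule="unstructured_scheme")
    return findings


def apply_schedule_rules(
    schedule: MedicationSchedule,
    drugref: DrugReference,
    kb: KnowledgeBase,
    config: DetectionConfig,
) -> list[Finding]:
    """Whole-plan rules: polypharmacy line count and duplicate ingredients."""
    findings = []
    n = len(schedule.rows)
    if n >= config.polypharmacy_threshold:
        findings.append(
            Finding(
                factor_id="total_number_of_drugs",
                row_indices=(),
                evidence=Evidence.make(
                    "line_count", count=n, threshold=config.polypharmacy_threshold
                ),
            )
        )
    row_ingredients = []
    for row in schedule.rows:
        record = drugref.lookup(row.pzn) if row.pzn else None
        if record is not None and record.active_ingredients:
            row_ingredients.append(set(record.active_ingredients))
        else:
            row_ingredients.append(set(row.ingredients()))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = schedule.rows[i].pzn, schedule.rows[j].pzn
            if not pi or not pj or pi == pj:
                continue
            shared = row_ingredients[i] & row_ingredients[j]
            if shared:
                findings.append(
                    Finding(
                        factor_id="same_ingredient_different_preparations",
                        row_indices=(i, j),
                        evidence=Evidence.make(
                            "ingredient_pair",
                            ingredient=sorted(shared)[0],
                            pzns=(pi, pj),
                        ),
                    )
                )
    return findings


def apply_keyword_rules(
    row_index: int,
    row: MedicationRow,
    lexicon: KeywordLexicon,
    kb: KnowledgeBase,
) -> list[Finding]:
    """Free-text rules: one finding per keyword factor per row with a hit.

    The as-needed (PRN) factor also fires on the row's PRN flag, keyword or
    not, since the plan format has a dedicated as-needed section.
    """
    findings = []
    keyword_factors = [f for f in kb.factors if f.mechanism == "keywords"]
    for f in keyword_factors:
        entry = lexicon.entries.get(f.factor_id)
        hits = []
        if entry is not None:
            hits = [(phrase, "instructions", span) for phrase, span in match_keywords(row.instructions, entry.phrases)]
            if entry.scan_scheme_text and not row.scheme.structured:
                hits += [
                    (phrase, "scheme_text", span)
                    for phrase, span in match_keywords(row.scheme_text, entry.phrases)
                ]
        flag_hit = f.factor_id == "prn" and row.prn
        if hits or flag_hit:
            findings.append(
                Finding(
                    factor_id=f.factor_id,
                    row_indices=(row_index,),
                    evidence=Evidence.make(
                        "matched_keyword",
                        matches=tuple((p, field_) for p, field_, _ in hits),
                        spans=tuple(span for _, _, span in hits),
                        prn_flag=flag_hit,
                    ),
                )
            )
    return findings


# ---------------------------------------------------------------------------
# the combined detector
# ---------------------------------------------------------------------------


def detect(
    schedule: MedicationSchedule,
    drugref: DrugReference,
    kb: KnowledgeBase,
    config: Optional[DetectionConfig] = None,
    lexicon: Optional[KeywordLexicon] = None,
    warnings: Optional[list[str]] = None,
) -> list[Finding]:
    """Run all four rule families and return the deduplicated finding list.

    Each automated factor fires at most once per row (schedule-level factors
    at most once per schedule; duplicate-ingredient findings once per row
    pair). The result is deterministically ordered by first triggering row,
    then catalogue position. ``warnings``, if given, collects row-level
    notes such as unresolvable PZNs.
    """
    if not schedule.rows:
        raise ValueError("cannot analyse an empty schedule")
    config = config or DetectionConfig()
    lexicon = lexicon or load_lexicon(language=config.language)
    warn = warnings if warnings is not None else []

    collected: list[Finding] = []
    for i, row in enumerate(schedule.rows):
        record = drugref.lookup(row.pzn) if row.pzn else None
        if record is None:
            msg = (
                f"row {i + 1}: PZN {row.pzn!r} not in drug reference; PZN rules skipped"
                if row.pzn
                else f"row {i + 1}: no PZN; PZN rules skipped"
            )
            if config.missing_pzn_is_error:
                raise ValueError(msg)
            warn.append(msg)
        else:
            collected += apply_pzn_rules(i, row, record, kb, lexicon)
        collected += apply_scheme_rules(i, row, record, schedule, kb)
        collected += apply_keyword_rules(i, row, lexicon, kb)
    collected += apply_schedule_rules(schedule, drugref, kb, config)

    seen = set()
    unique = []
    for f in collected:
        key = (f.factor_id, f.row_indices)
        if key not in seen:
            seen.add(key)
            unique.append(f)
    order = {fid: k for k, fid in enumerate(kb.factor_ids)}
    unique.sort(
        key=lambda f: (
            f.row_indices[0] if f.row_indices else -1,
            order.get(f.factor_id, len(order)),
            f.row_indices,
        )
    )
    return unique
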