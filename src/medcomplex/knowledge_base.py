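"""The complexity-factor catalogue: loader, validator, and summary statistics.

The knowledge base is a single human-editable YAML file packaged with the
library (``data/knowledge_base.yaml``). It holds three registries:

* **factors** — the 61 complexity-factor records in six categories
  (dosage form, dosage scheme, additional instructions, patient, product,
  process). 38 factors are automatically detectable from a medication
  schedule; nine are deliberately out of the tool's scope and carry no
  questions or measures.
* **questions** — the question bank: *key* questions bound to automated
  findings, eight *distinct* questions asked in every interview, and one
  *open* question asked last. Questions may have several parts, each with
  its own answer type and problem predicate.
* **measures** — optimisation-measure registry: recommendations for action
  (three topics), training-material stubs, and the five substitution
  algorithms.

Counts are never hard-coded: :func:`kb_stats` enumerates the loaded records,
and :func:`validate_kb` cross-checks every structural invariant, returning
violations as data so a caller can render them all at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

CATEGORIES = (
    "dosage_form",
    "dosage_scheme",
    "additional_instructions",
    "patient",
    "product",
    "process",
)
MECHANISMS = ("pzn", "dosage_scheme", "schedule_lines", "keywords", "pzn_and_keywords")
QUESTION_KINDS = ("key", "distinct", "open")
ANSWER_TYPES = ("yes_no", "numeric", "free_text")
MEASURE_TYPES = ("recommendation_for_action", "training_material", "algorithm")
RECOMMENDATION_TOPICS = ("aid_suggestion", "explain_administration", "review_regimen")
PREDICATES = (
    "yes_is_problem",
    "no_is_problem",
    "numeric_below",
    "numeric_above",
    "informational",
    "note_only",
)

#: number of factors the packaged catalogue must contain
EXPECTED_FACTORS = 61
#: number of distinct substitution algorithms in the measure registry
EXPECTED_ALGORITHMS = 5
#: number of distinct questions in the question bank
EXPECTED_DISTINCT_QUESTIONS = 8


class KBLoadError(ValueError):
    """Raised when the KB file cannot be parsed into records."""


class KBIntegrityError(ValueError):
    """Raised when a loaded KB violates a catalogue invariant."""


@dataclass(frozen=True)
class Predicate:
    """Named rule deciding whether an answer confirms a problem."""

    name: str
    threshold: Optional[float] = None


@dataclass(frozen=True)
class QuestionPart:
    text: str
    answer_type: str
    predicate: Predicate


@dataclass(frozen=True)
class Question:
    question_id: str
    kind: str
    parts: tuple[QuestionPart, ...]
    device_subtypes: tuple[str, ...] = ()
    #: factor ids referencing this question; filled in during cross-linking
    shared_by: tuple[str, ...] = ()


@dataclass(frozen=True)
class Measure:
    measure_id: str
    type: str
    title: str = ""
    topic: Optional[str] = None
    resource_ref: Optional[str] = None
    algorithm_ref: Optional[str] = None


@dataclass(frozen=True)
class ComplexityFactor:
    factor_id: str
    label: str
    category: str
    automated: bool
    in_tool: bool
    mechanism: Optional[str] = None
    device_subtypes: tuple[str, ...] = ()
    question_ids: tuple[str, ...] = ()
    measure_ids: tuple[str, ...] = ()


@dataclass
class KnowledgeBase:
    """Cross-linked catalogue: ordered factors plus question/measure banks."""

    factors: list[ComplexityFactor]
    questions: dict[str, Question]
    measures: dict[str, Measure]
    language: str = "en"
    version: int = 1

    def factor(self, factor_id: str) -> ComplexityFactor:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise KeyError(factor_id)

    @property
    def factor_ids(self) -> list[str]:
        return [f.factor_id for f in self.factors]

    def factor_order(self, factor_id: str) -> int:
        """Stable catalogue position, used for deterministic ordering."""
        return self.factor_ids.index(factor_id)

    def automated_factors(self) -> list[ComplexityFactor]:
        return [f for f in self.factors if f.automated]


@dataclass(frozen=True)
class KBStats:
    n_factors: int
    n_automated: int
    n_not_automated: int
    n_in_tool: int
    n_per_category: dict[str, int]
    n_distinct_questions: int
    n_algorithms: int
    n_not_considered: int


def default_kb_path() -> Path:
    return Path(str(resources.files("medcomplex").joinpath("data/knowledge_base.yaml")))


def _as_tuple(value) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, str):
        return (value,)
    return tuple(value)


def _parse_question(raw: dict) -> Question:
    qid = raw.get("id")
    if not qid:
        raise KBLoadError("question record without an id")
    parts = []
    for i, p in enumerate(raw.get("parts") or []):
        pred_raw = p.get("predicate") or {}
        pred = Predicate(
            name=pred_raw.get("name", ""),
            threshold=pred_raw.get("threshold"),
        )
        if "text" not in p or "answer_type" not in p:
            raise KBLoadError(f"question {qid!r}: part {i} missing text/answer_type")
        parts.append(QuestionPart(text=p["text"].strip(), answer_type=p["answer_type"], predicate=pred))
    if not parts:
        raise KBLoadError(f"question {qid!r} has no parts")
    return Question(
        question_id=qid,
        kind=raw.get("kind", ""),
        parts=tuple(parts),
        device_subtypes=_as_tuple(raw.get("device_subtypes")),
    )


def _parse_measure(raw: dict) -> Measure:
    mid = raw.get("id")
    if not mid:
        raise KBLoadError("measure record without an id")
    return Measure(
        measure_id=mid,
        type=raw.get("type", ""),
        title=raw.get("title", ""),
        topic=raw.get("topic"),
        resource_ref=raw.get("resource_ref"),
        algorithm_ref=raw.get("algorithm_ref"),
    )


def _parse_factor(raw: dict) -> ComplexityFactor:
    fid = raw.get("id")
    if not fid:
        raise KBLoadError("factor record without an id")
    return ComplexityFactor(
        factor_id=fid,
        label=raw.get("label", fid),
        category=raw.get("category", ""),
        automated=bool(raw.get("automated", False)),
        in_tool=bool(raw.get("in_tool", False)),
        mechanism=raw.get("mechanism"),
        device_subtypes=_as_tuple(raw.get("device_subtypes")),
        question_ids=_as_tuple(raw.get("questions")),
        measure_ids=_as_tuple(raw.get("measures")),
    )


def load_knowledge_base(
    path: Union[str, Path, None] = None, *, validate: bool = True
) -> KnowledgeBase:
    """Load (and by default validate) a knowledge-base file.

    Parameters
    ----------
    path:
        YAML file to load; ``None`` selects the packaged catalogue.
    validate:
        When true (default), every catalogue invariant is checked and a
        :class:`KBIntegrityError` listing all violations is raised if any
        fail. Tests may pass ``validate=False`` to build deliberately
        non-conforming catalogues.
    """
    kb_path = Path(path) if path is not None else default_kb_path()
    try:
        doc = yaml.safe_load(kb_path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise KBLoadError(f"cannot parse {kb_path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise KBLoadError(f"{kb_path}: expected a mapping at top level")

    factors = [_parse_factor(r) for r in doc.get("factors") or []]
    questions = {}
    for r in doc.get("questions") or []:
        q = _parse_question(r)
        if q.question_id in questions:
            raise KBLoadError(f"duplicate question id {q.question_id!r}")
        questions[q.question_id] = q
    measures = {}
    for r in doc.get("measures") or []:
        m = _parse_measure(r)
        if m.measure_id in measures:
            raise KBLoadError(f"duplicate measure id {m.measure_id!r}")
        measures[m.measure_id] = m

    kb = KnowledgeBase(
        factors=factors,
        questions=questions,
        measures=measures,
        language=doc.get("language", "en"),
        version=doc.get("version", 1),
    )
    _cross_link(kb)
    if validate:
        violations = validate_kb(kb)
        if violations:
            raise KBIntegrityError(
                "knowledge base failed validation:\n  - " + "\n  - ".join(violations)
            )
    return kb


def _cross_link(kb: KnowledgeBase) -> None:
    """Fill each question's shared_by list from the factor records."""
    by_question: dict[str, list[str]] = {}
    for f in kb.factors:
        for qid in f.question_ids:
            by_question.setdefault(qid, []).append(f.factor_id)
    for qid, q in kb.questions.items():
        object.__setattr__(q, "shared_by", tuple(by_question.get(qid, ())))


def validate_kb(kb: KnowledgeBase) -> list[str]:
    """Check every catalogue invariant; violations are returned, not raised."""
    v: list[str] = []
    seen: set[str] = set()
    for f in kb.factors:
        where = f"factor {f.factor_id!r}"
        if f.factor_id in seen:
            v.append(f"{where}: duplicate id")
        seen.add(f.factor_id)
        if f.category not in CATEGORIES:
            v.append(f"{where}: unknown category {f.category!r}")
        if f.automated:
            if f.mechanism not in MECHANISMS:
                v.append(f"{where}: automated but mechanism {f.mechanism!r} invalid")
            if not f.in_tool:
                v.append(f"{where}: automated factors must be in the tool")
        elif f.mechanism is not None:
            v.append(f"{where}: mechanism set on a non-automated factor")
        if f.in_tool:
            if not f.question_ids:
                v.append(f"{where}: in-tool factor without a question")
            if not f.measure_ids:
                v.append(f"{where}: in-tool factor without a measure")
        else:
            if f.question_ids or f.measure_ids:
                v.append(f"{where}: 'not considered in tool' factor carries questions/measures")
        for qid in f.question_ids:
            if qid not in kb.questions:
                v.append(f"{where}: dangling question reference {qid!r}")
        for mid in f.measure_ids:
            if mid not in kb.measures:
                v.append(f"{where}: dangling measure reference {mid!r}")

    if len(kb.factors) != EXPECTED_FACTORS:
        v.append(f"catalogue: expected {EXPECTED_FACTORS} factors, found {len(kb.factors)}")

    n_distinct = sum(1 for q in kb.questions.values() if q.kind == "distinct")
    n_open = sum(1 for q in kb.questions.values() if q.kind == "open")
    if n_distinct != EXPECTED_DISTINCT_QUESTIONS:
        v.append(
            f"question bank: expected {EXPECTED_DISTINCT_QUESTIONS} distinct questions, "
            f"found {n_distinct}"
        )
    if n_open != 1:
        v.append(f"question bank: expected exactly 1 open question, found {n_open}")

    automated_qids = {
        qid for f in kb.factors if f.automated for qid in f.question_ids
    }
    for q in kb.questions.values():
        where = f"question {q.question_id!r}"
        if q.kind not in QUESTION_KINDS:
            v.append(f"{where}: unknown kind {q.kind!r}")
        if q.kind == "key" and q.question_id not in automated_qids:
            v.append(f"{where}: key question not referenced by any automated factor")
        for i, part in enumerate(q.parts):
            if part.answer_type not in ANSWER_TYPES:
                v.append(f"{where}: part {i} has unknown answer_type {part.answer_type!r}")
            if part.predicate.name not in PREDICATES:
                v.append(f"{where}: part {i} has unknown predicate {part.predicate.name!r}")
            if part.predicate.name in ("numeric_below", "numeric_above"):
                if part.answer_type != "numeric" or part.predicate.threshold is None:
                    v.append(f"{where}: part {i} numeric predicate misconfigured")

    algorithm_refs = set()
    for m in kb.measures.values():
        where = f"measure {m.measure_id!r}"
        if m.type not in MEASURE_TYPES:
            v.append(f"{where}: unknown type {m.type!r}")
        if m.type == "recommendation_for_action" and m.topic not in RECOMMENDATION_TOPICS:
            v.append(f"{where}: recommendation without a valid topic")
        if m.type == "algorithm":
            if not m.algorithm_ref:
                v.append(f"{where}: algorithm measure without algorithm_ref")
            else:
                algorithm_refs.add(m.algorithm_ref)
    if kb.measures and len(algorithm_refs) != EXPECTED_ALGORITHMS:
        v.append(
            f"measure registry: expected {EXPECTED_ALGORITHMS} algorithms, "
            f"found {len(algorithm_refs)}"
        )
    return v


def kb_stats(kb: KnowledgeBase) -> KBStats:
    """Summary counts, computed by enumerating the loaded records."""
    n_per_category = {c: 0 for c in CATEGORIES}
    n_automated = 0
    n_in_tool = 0
    n_not_considered = 0
    for f in kb.factors:
        if f.category in n_per_category:
            n_per_category[f.category] += 1
        if f.automated:
            n_automated += 1
        if f.in_tool:
            n_in_tool += 1
        else:
            n_not_considered += 1
    return KBStats(
        n_factors=len(kb.factors),
        n_automated=n_automated,
        n_not_automated=len(kb.factors) - n_automated,
        n_in_tool=n_in_tool,
        n_per_category=n_per_category,
        n_distinct_questions=sum(1 for q in kb.questions.values() if q.kind == "distinct"),
        n_algorithms=len(
            {m.algorithm_ref for m in kb.measures.values() if m.type == "algorithm"}
        ),
        n_not_considered=n_not_considered,
    )


def serialize_kb(kb: KnowledgeBase) -> dict:
    """Plain-dict form of the catalogue, suitable for YAML round-tripping."""
    return {
        "version": kb.version,
        "language": kb.language,
        "factors": [
            {
                "id": f.factor_id,
                "label": f.label,
                "category": f.category,
                "automated": f.automated,
                "in_tool": f.in_tool,
                **({"mechanism": f.mechanism} if f.mechanism else {}),
                **({"device_subtypes": list(f.device_subtypes)} if f.device_subtypes else {}),
                **({"questions": list(f.question_ids)} if f.question_ids else {}),
                **({"measures": list(f.measure_ids)} if f.measure_ids else {}),
            }
            for f in kb.factors
        ],
        "questions": [
            {
                "id": q.question_id,
                "kind": q.kind,
                **({"device_subtypes": list(q.device_subtypes)} if q.device_subtypes else {}),
                "parts": [
                    {
                        "text": p.text,
                        "answer_type": p.answer_type,
                        "predicate": {
                            "name": p.predicate.name,
                            **(
                                {"threshold": p.predicate.threshold}
                                if p.predicate.threshold is not None
                                else {}
                            ),
                        },
                    }
                    for p in q.parts
                ],
            }
            for q in kb.questions.values()
        ],
        "measures": [
            {
                "id": m.measure_id,
                "type": m.type,
                **({"title": m.title} if m.title else {}),
                **({"topic": m.topic} if m.topic else {}),
                **({"resource_ref": m.resource_ref} if m.resource_ref else {}),
                **({"algorithm_ref": m.algorithm_ref} if m.algorithm_ref else {}),
            }
            for m in kb.measures.values()
        ],
    }
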