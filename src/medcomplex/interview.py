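"""Personalising findings through patient questions.

Every automated finding gets its factor's key question(s), instantiated per
triggering row so the interviewer can point at the concrete drug; device
subtypes (e.g. the inhaler type) select the device-specific variant. The
eight distinct questions are asked in every interview regardless of
findings, each only once even when it covers several factors, and the
open-ended question always comes last.

Answers are evaluated by the per-part problem predicates stored in the
knowledge base (the phrasings mix problem-affirming "Do you have
problems…?" and competence-affirming "Do you always succeed…?" questions,
so polarity is data, not a global rule; multi-part questions confirm on any
problematic part). Open-question text is stored verbatim as a note and is
never auto-mapped to a factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .detection import Finding
from .knowledge_base import KnowledgeBase, Question

YES_VALUES = ("yes", "y", "true", "1")
NO_VALUES = ("no", "n", "false", "0")


class InterviewError(ValueError):
    pass


@dataclass(frozen=True)
class QuestionInstance:
    instance_id: str
    question_id: str
    kind: str
    factor_ids: tuple[str, ...]
    row_indices: tuple[int, ...]
    texts: tuple[str, ...]
    answer_types: tuple[str, ...]

    @property
    def rendered(self) -> str:
        return " ".join(self.texts)


@dataclass(frozen=True)
class Answer:
    instance_id: str
    #: scalar for single-part questions, sequence for multi-part ones
    value: object


@dataclass(frozen=True)
class ConfirmedFactor:
    factor_id: str
    row_indices: tuple[int, ...]
    source: str  # automated+answer | distinct_question


@dataclass(frozen=True)
class ConfirmedFactorSet:
    confirmed: tuple[ConfirmedFactor, ...]
    free_text_notes: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(c.factor_id for c in self.confirmed)


def _select_key_questions(question_ids: Sequence[str], kb: KnowledgeBase, subtype: Optional[str]) -> list[Question]:
    """Pick the device-specific variant(s) for a finding's subtype.

    Questions without a device restriction always apply. If the factor only
    has subtype-specific variants and the finding carries no (or an unknown)
    subtype, the generic "other"-device variant is used when one exists,
    otherwise the first listed variant.
    """
    questions = [kb.questions[qid] for qid in question_ids]
    unrestricted = [q for q in questions if not q.device_subtypes]
    matching = [q for q in questions if q.device_subtypes and subtype in q.device_subtypes]
    if matching or unrestricted:
        return unrestricted + matching
    fallback = [
        q for q in questions if any(s.startswith("other") for s in q.device_subtypes)
    ]
    return fallback or questions[:1]


def build_question_set(findings: Sequence[Finding], kb: KnowledgeBase) -> list[QuestionInstance]:
    """Ordered interview: key questions per finding row, then the distinct
    block, then the open question."""
    instances: list[QuestionInstance] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()
    for f in findings:
        factor = kb.factor(f.factor_id)
        if not factor.question_ids:
            raise InterviewError(
                f"finding for factor {f.factor_id!r} has no key question in the KB"
            )
        for q in _select_key_questions(factor.question_ids, kb, f.device_subtype):
            key = (q.question_id, f.row_indices)
            if key in seen:
                continue
            seen.add(key)
            suffix = ",".join(str(i) for i in f.row_indices)
            instances.append(
                QuestionInstance(
                    instance_id=f"{q.question_id}@{suffix}" if suffix else q.question_id,
                    question_id=q.question_id,
                    kind="key",
                    factor_ids=(f.factor_id,),
                    row_indices=f.row_indices,
                    texts=tuple(p.text for p in q.parts),
                    answer_types=tuple(p.answer_type for p in q.parts),
                )
            )
    for q in kb.questions.values():
        if q.kind == "distinct":
            instances.append(
                QuestionInstance(
                    instance_id=q.question_id,
                    question_id=q.question_id,
                    kind="distinct",
                    factor_ids=q.shared_by,
                    row_indices=(),
                    texts=tuple(p.text for p in q.parts),
                    answer_types=tuple(p.answer_type for p in q.parts),
                )
            )
    open_qs = [q for q in kb.questions.values() if q.kind == "open"]
    for q in open_qs:
        instances.append(
            QuestionInstance(
                instance_id=q.question_id,
                question_id=q.question_id,
                kind="open",
                factor_ids=(),
                row_indices=(),
                texts=tuple(p.text for p in q.parts),
                answer_types=tuple(p.answer_type for p in q.parts),
            )
        )
    return instances


def _coerce_yes_no(value: object, instance_id: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        v = value.strip().lower()
        if v in YES_VALUES:
            return True
        if v in NO_VALUES:
            return False
    raise InterviewError(f"answer for {instance_id!r}: expected yes/no, got {value!r}")


def _coerce_numeric(value: object, instance_id: str) -> float:
    if isinstance(value, bool):
        raise InterviewError(f"answer for {instance_id!r}: expected a number, got {value!r}")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        try:
            return float(value.strip().replace(",", "."))
        except ValueError:
            pass
    raise InterviewError(f"answer for {instance_id!r}: expected a number, got {value!r}")


def _part_is_problem(part, value, instance_id: str) -> bool:
    pred = part.predicate
    if pred.name in ("informational", "note_only"):
        return False
    if part.answer_type == "yes_no":
        answered_yes = _coerce_yes_no(value, instance_id)
        if pred.name == "yes_is_problem":
            return answered_yes
        if pred.name == "no_is_problem":
            return not answered_yes
    if part.answer_type == "numeric":
        number = _coerce_numeric(value, instance_id)
        if pred.name == "numeric_below":
            return number < pred.threshold
        if pred.name == "numeric_above":
            return number > pred.threshold
    raise InterviewError(
        f"answer for {instance_id!r}: predicate {pred.name!r} does not fit "
        f"answer type {part.answer_type!r}"
    )


def resolve(
    question_set: Sequence[QuestionInstance],
    answers: Sequence[Answer],
    kb: KnowledgeBase,
) -> ConfirmedFactorSet:
    """Evaluate answers against their predicates; order-independent and pure.

    Unanswered non-open questions are treated as not-confirmed with a
    warning. A factor confirmed by several instances is reported once with
    the union of its triggering rows.
    """
    by_instance = {}
    for a in answers:
        by_instance[a.instance_id] = a
    warnings = []
    notes = []
    confirmed: dict[str, dict] = {}

    for inst in question_set:
        answer = by_instance.get(inst.instance_id)
        question = kb.questions[inst.question_id]
        if inst.kind == "open":
            if answer is not None and str(answer.value).strip():
                notes.append(str(answer.value).strip())
            continue
        if answer is None:
            warnings.append(f"question {inst.instance_id!r} unanswered; treated as no problem")
            continue
        values = answer.value
        if len(question.parts) == 1:
            values = [values]
        elif not isinstance(values, (list, tuple)) or len(values) != len(question.parts):
            raise InterviewError(
                f"answer for {inst.instance_id!r}: expected {len(question.parts)} "
                f"sub-answers, got {answer.value!r}"
            )
        problem = any(
            _part_is_problem(part, value, inst.instance_id)
            for part, value in zip(question.parts, values)
        )
        if not problem:
            continue
        source = "automated+answer" if inst.kind == "key" else "distinct_question"
        for fid in inst.factor_ids:
            slot = confirmed.setdefault(fid, {"rows": set(), "source": source})
            slot["rows"].update(inst.row_indices)

    order = {fid: k for k, fid in enumerate(kb.factor_ids)}
    result = tuple(
        ConfirmedFactor(
            factor_id=fid,
            row_indices=tuple(sorted(slot["rows"])),
            source=slot["source"],
        )
        for fid, slot in sorted(confirmed.items(), key=lambda kv: order.get(kv[0], len(order)))
    )
    return ConfirmedFactorSet(
        confirmed=result, free_text_notes=tuple(notes), warnings=tuple(warnings)
    )
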