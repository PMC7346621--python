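"""Optimisation measures for confirmed factors, including the five
alternative-drug suggestion algorithms.

Measures come in three kinds: recommendations for action (aid suggestion,
administration explanation, regimen review), training-material stubs, and
algorithms. The five algorithms operate on the curated equivalence groups
of the drug reference and never invent products:

* **alternative_strength** — a product strength equal to the per-slot
  administered dose, so split tablets or multiple concurrent units become
  one whole unit.
* **alternative_form** — an easier-to-administer sibling (liquid oral or
  orodispersible) at equivalent strength, for swallowing or crushing
  problems.
* **frequency_reduction** — an extended-release sibling whose strength
  packs the same daily dose into fewer administrations.
* **combination_product** — a fixed-dose combination replacing two schedule
  rows with matching ingredients, strengths and schemes.
* **prefilled_device** — a prefilled injector sibling of a non-prefilled
  injection at the same ingredient and strength.

Suggestions are advisory: the planner never mutates the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .drug_reference import DrugRecord, DrugReference, find_alternatives
from .interview import ConfirmedFactorSet
from .knowledge_base import KnowledgeBase
from .schedule_io import MedicationRow, MedicationSchedule

_MEASURE_TYPE_ORDER = {"algorithm": 0, "recommendation_for_action": 1, "training_material": 2}


@dataclass(frozen=True)
class Suggestion:
    record: DrugRecord
    rationale: str
    row_indices: tuple[int, ...] = ()


@dataclass(frozen=True)
class PlanEntry:
    factor_id: str
    row_indices: tuple[int, ...]
    measure_id: str
    measure_type: str
    #: suggestions for algorithms, rendered text for recommendations,
    #: resource stub for training material
    payload: dict


@dataclass(frozen=True)
class MeasurePlan:
    entries: tuple[PlanEntry, ...]


# ---------------------------------------------------------------------------
# the five algorithms
# ---------------------------------------------------------------------------


def alg_alternative_strength(
    row: MedicationRow, record: Optional[DrugRecord], drugref: DrugReference
) -> list[Suggestion]:
    """A1: match product strength to the administered per-slot dose."""
    if record is None or record.strength_mg is None or not record.equivalence_group:
        return []
    if not row.scheme.structured:
        return []
    suggestions = []
    seen = set()
    for dose in sorted({s for s in row.scheme.slots if s > 0}):
        fractional = dose != int(dose)
        stacked = dose >= 2
        if not fractional and not stacked:
            continue
        target = dose * record.strength_mg
        for alt in find_alternatives(
            drugref,
            record.equivalence_group,
            exclude_pzn=record.pzn,
            form_class="solid_oral",
            strength_mg=target,
        ):
            if alt.pzn in seen:
                continue
            seen.add(alt.pzn)
            why = (
                f"one unit of {alt.brand_name} ({target:g} mg) replaces "
                f"{dose:g} x {record.strength_mg:g} mg of {record.brand_name}"
            )
            suggestions.append(Suggestion(record=alt, rationale=why))
    return suggestions


def alg_alternative_form(
    row: MedicationRow, record: Optional[DrugRecord], drugref: DrugReference
) -> list[Suggestion]:
    """A2: easier-administration sibling (liquid oral or orodispersible)."""
    if record is None or not record.equivalence_group:
        return []
    if record.form_class == "liquid_oral" or record.orodispersible:
        return []
    out = []
    for alt in find_alternatives(
        drugref,
        record.equivalence_group,
        exclude_pzn=record.pzn,
        strength_mg=record.strength_mg,
    ):
        if alt.form_class == "liquid_oral" or alt.orodispersible:
            kind = "liquid" if alt.form_class == "liquid_oral" else "orodispersible"
            out.append(
                Suggestion(
                    record=alt,
                    rationale=f"{alt.brand_name} is a {kind} alternative to {record.brand_name}",
                )
            )
    return out


def alg_frequency_reduction(
    row: MedicationRow, record: Optional[DrugRecord], drugref: DrugReference
) -> list[Suggestion]:
    """A3: extended-release sibling packing the daily dose into fewer slots."""
    if record is None or record.strength_mg is None or not record.equivalence_group:
        return []
    if not row.scheme.structured:
        return []
    nonzero = row.scheme.nonzero_slots
    if nonzero <= 1:
        return []
    daily = sum(row.scheme.slots) * record.strength_mg
    out = []
    for alt in find_alternatives(
        drugref,
        record.equivalence_group,
        exclude_pzn=record.pzn,
        extended_release=True,
    ):
        if not alt.strength_mg:
            continue
        units = daily / alt.strength_mg
        if abs(units - round(units)) > 1e-9 or round(units) >= nonzero or units <= 0:
            continue
        out.append(
            Suggestion(
                record=alt,
                rationale=(
                    f"{int(round(units))} administration(s) of {alt.brand_name} "
                    f"({alt.strength_mg:g} mg ER) cover the {daily:g} mg daily dose "
                    f"now split over {nonzero} time points"
                ),
            )
        )
    return out


def alg_combination_product(
    schedule: MedicationSchedule, drugref: DrugReference
) -> list[Suggestion]:
    """A4: fixed-dose combination replacing two rows with one.

    Requires single-ingredient records for both rows, identical structured
    schemes, and a combination record containing exactly those ingredients
    at the strengths prescribed.
    """
    records = [drugref.lookup(r.pzn) if r.pzn else None for r in schedule.rows]
    combos = [
        rec
        for rec in sorted(drugref.records, key=lambda r: r.pzn)
        if len(rec.active_ingredients) == 2 and len(rec.component_strengths_mg) == 2
    ]
    out = []
    n = len(schedule.rows)
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = records[i], records[j]
            if ri is None or rj is None:
                continue
            if len(ri.active_ingredients) != 1 or len(rj.active_ingredients) != 1:
                continue
            if ri.strength_mg is None or rj.strength_mg is None:
                continue
            si, sj = schedule.rows[i].scheme, schedule.rows[j].scheme
            if not (si.structured and sj.structured and si.slots == sj.slots):
                continue
            pair = {
                ri.active_ingredients[0]: ri.strength_mg,
                rj.active_ingredients[0]: rj.strength_mg,
            }
            for combo in combos:
                wanted = dict(zip(combo.active_ingredients, combo.component_strengths_mg))
                if wanted == pair:
                    out.append(
                        Suggestion(
                            record=combo,
                            row_indices=(i, j),
                            rationale=(
                                f"{combo.brand_name} combines {ri.brand_name} and "
                                f"{rj.brand_name}, reducing the schedule by one line"
                            ),
                        )
                    )
    return out


def alg_prefilled_device(
    row: MedicationRow, record: Optional[DrugRecord], drugref: DrugReference
) -> list[Suggestion]:
    """A5: prefilled injector sibling at the same ingredient and strength."""
    if record is None or not record.equivalence_group:
        return []
    if record.device_subtype == "prefilled_injector":
        return []
    out = []
    for alt in find_alternatives(
        drugref,
        record.equivalence_group,
        exclude_pzn=record.pzn,
        device_subtype="prefilled_injector",
        strength_mg=record.strength_mg,
    ):
        if set(alt.active_ingredients) != set(record.active_ingredients):
            continue
        out.append(
            Suggestion(
                record=alt,
                rationale=f"{alt.brand_name} is a prefilled device for {record.brand_name}",
            )
        )
    return out


ALGORITHMS = {
    "alternative_strength": alg_alternative_strength,
    "alternative_form": alg_alternative_form,
    "frequency_reduction": alg_frequency_reduction,
    "combination_product": alg_combination_product,
    "prefilled_device": alg_prefilled_device,
}


def _run_algorithm(
    algorithm_ref: str,
    row_indices: tuple[int, ...],
    schedule: MedicationSchedule,
    drugref: DrugReference,
) -> list[Suggestion]:
    if algorithm_ref == "combination_product":
        return alg_combination_product(schedule, drugref)
    fn = ALGORITHMS[algorithm_ref]
    out = []
    for i in row_indices:
        row = schedule.rows[i]
        record = drugref.lookup(row.pzn) if row.pzn else None
        for s in fn(row, record, drugref):
            out.append(Suggestion(record=s.record, rationale=s.rationale, row_indices=(i,)))
    return out


def _suggestion_payload(suggestions: Sequence[Suggestion]) -> dict:
    if not suggestions:
        return {"suggestions": [], "note": "no alternative found"}
    return {
        "suggestions": [
            {
                "pzn": s.record.pzn,
                "brand_name": s.record.brand_name,
                "strength_mg": s.record.strength_mg,
                "form_class": s.record.form_class,
                "rows": list(s.row_indices),
                "rationale": s.rationale,
            }
            for s in suggestions
        ]
    }


def plan(
    confirmed: ConfirmedFactorSet,
    schedule: MedicationSchedule,
    drugref: DrugReference,
    kb: KnowledgeBase,
) -> MeasurePlan:
    """Instantiate every measure of every confirmed factor.

    Algorithm measures are executed immediately against the drug reference;
    an algorithm with no applicable alternative degrades to a
    "no alternative found" note so the factor's other measures still stand.
    Ordering is deterministic: confirmed-factor (catalogue) order, then
    measure type (algorithm, recommendation, training material).
    """
    entries = []
    for cf in confirmed.confirmed:
        factor = kb.factor(cf.factor_id)
        measures = sorted(
            (kb.measures[mid] for mid in factor.measure_ids),
            key=lambda m: (_MEASURE_TYPE_ORDER.get(m.type, 9), m.measure_id),
        )
        for m in measures:
            if m.type == "algorithm":
                suggestions = _run_algorithm(m.algorithm_ref, cf.row_indices, schedule, drugref)
                payload = _suggestion_payload(suggestions)
            elif m.type == "recommendation_for_action":
                payload = {"topic": m.topic, "instruction": m.title}
            else:
                payload = {"resource_ref": m.resource_ref, "title": m.title}
            entries.append(
                PlanEntry(
                    factor_id=cf.factor_id,
                    row_indices=cf.row_indices,
                    measure_id=m.measure_id,
                    measure_type=m.type,
                    payload=payload,
                )
            )
    return MeasurePlan(entries=tuple(entries))
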