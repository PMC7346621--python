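"""Measure planning and the five alternative-drug algorithms."""

import pytest

from medcomplex.detection import detect
from medcomplex.drug_reference import find_alternatives
from medcomplex.interview import Answer, build_question_set, resolve
from medcomplex.recommender import (
    ALGORITHMS,
    alg_alternative_form,
    alg_alternative_strength,
    alg_combination_product,
    alg_frequency_reduction,
    alg_prefilled_device,
    plan,
)

from .conftest import make_schedule, reduction_scenarios, row_for


def _confirm(schedule, drugref, kb, answers):
    findings = detect(schedule, drugref, kb)
    instances = build_question_set(findings, kb)
    return resolve(instances, answers, kb)


def test_half_dose_suggests_half_strength_product(drugref):
    row = row_for(drugref, "04773415", scheme_text="0.5-0-0.5-0")  # 10 mg halved
    out = alg_alternative_strength(row, drugref.lookup(row.pzn), drugref)
    assert [s.record.pzn for s in out] == ["04773414"]  # the 5 mg sibling
    assert "5 mg" in out[0].rationale


def test_stacked_dose_suggests_double_strength_product(drugref):
    row = row_for(drugref, "01000011", scheme_text="2-0-0-0")  # 2 x 5 mg
    out = alg_alternative_strength(row, drugref.lookup(row.pzn), drugref)
    assert [s.record.pzn for s in out] == ["01000012"]  # the 10 mg sibling


def test_no_matching_strength_yields_empty(drugref):
    row = row_for(drugref, "04773414", scheme_text="0.5-0-0-0")  # 2.5 mg not in group
    assert alg_alternative_strength(row, drugref.lookup(row.pzn), drugref) == []


def test_tablet_with_liquid_sibling_suggests_liquid(drugref):
    row = row_for(drugref, "01000031")
    out = alg_alternative_form(row, drugref.lookup(row.pzn), drugref)
    assert [s.record.pzn for s in out] == ["01000032"]


def test_orodispersible_sibling_counts_as_easier_form(drugref):
    row = row_for(drugref, "01000041")
    out = alg_alternative_form(row, drugref.lookup(row.pzn), drugref)
    assert [s.record.pzn for s in out] == ["01000042"]


def test_already_liquid_or_no_sibling_yields_empty(drugref):
    liquid = row_for(drugref, "01000032")
    assert alg_alternative_form(liquid, drugref.lookup(liquid.pzn), drugref) == []
    loner = row_for(drugref, "01000211")  # group has no liquid sibling
    assert alg_alternative_form(loner, drugref.lookup(loner.pzn), drugref) == []


def test_thrice_daily_suggests_extended_release_once_daily(drugref):
    row = row_for(drugref, "01000021", scheme_text="1-1-1-0")  # 3 x 100 mg
    out = alg_frequency_reduction(row, drugref.lookup(row.pzn), drugref)
    assert [s.record.pzn for s in out] == ["01000022"]  # 300 mg ER
    assert "1 administration" in out[0].rationale


def test_once_daily_needs_no_frequency_reduction(drugref):
    row = row_for(drugref, "01000021", scheme_text="1-0-0-0")
    assert alg_frequency_reduction(row, drugref.lookup(row.pzn), drugref) == []


def test_combination_product_for_matching_pair(drugref):
    schedule = make_schedule(
        row_for(drugref, "01000061", scheme_text="1-0-0-0"),
        row_for(drugref, "01000062", scheme_text="1-0-0-0"),
    )
    out = alg_combination_product(schedule, drugref)
    assert [s.record.pzn for s in out] == ["01000063"]
    assert out[0].row_indices == (0, 1)


def test_combination_requires_matching_strengths_and_schemes(drugref):
    mismatched_scheme = make_schedule(
        row_for(drugref, "01000061", scheme_text="1-0-0-0"),
        row_for(drugref, "01000062", scheme_text="0-0-1-0"),
    )
    assert alg_combination_product(mismatched_scheme, drugref) == []
    single = make_schedule(row_for(drugref, "01000061", scheme_text="1-0-0-0"))
    assert alg_combination_product(single, drugref) == []


def test_prefilled_sibling_suggested_for_vial(drugref):
    row = row_for(drugref, "01000051")
    out = alg_prefilled_device(row, drugref.lookup(row.pzn), drugref)
    assert [s.record.pzn for s in out] == ["01000052"]
    already = row_for(drugref, "01000052")
    assert alg_prefilled_device(already, drugref.lookup(already.pzn), drugref) == []


def test_algorithms_never_invent_products(drugref):
    """Every suggestion is a record of the reference table and, for the
    group-based algorithms, a member of the query's equivalence group."""
    cases = [
        (alg_alternative_strength, row_for(drugref, "04773415", scheme_text="0.5-0-0.5-0")),
        (alg_alternative_form, row_for(drugref, "01000031")),
        (alg_frequency_reduction, row_for(drugref, "01000021", scheme_text="1-1-1-0")),
        (alg_prefilled_device, row_for(drugref, "01000051")),
    ]
    for fn, row in cases:
        record = drugref.lookup(row.pzn)
        group = {r.pzn for r in find_alternatives(drugref, record.equivalence_group, exclude_pzn=row.pzn)}
        for s in fn(row, record, drugref):
            assert s.record.pzn in group
            assert s.record.pzn != row.pzn


def test_plan_orders_measures_and_degrades_without_alternative(drugref, kb):
    # swallowing difficulties confirmed via the distinct question on a drug
    # whose group offers no easier form: algorithm degrades to a note, the
    # recommendation and leaflet stand
    schedule = make_schedule(row_for(drugref, "01000211"))
    instances = build_question_set([], kb)
    swallow = next(i for i in instances if i.question_id == "dq_swallowing")
    confirmed = resolve(instances, [Answer(swallow.instance_id, "yes")], kb)
    result = plan(confirmed, schedule, drugref, kb)
    types = [e.measure_type for e in result.entries]
    assert types == ["algorithm", "recommendation_for_action", "training_material"]
    assert result.entries[0].payload == {"suggestions": [], "note": "no alternative found"}
    assert result.entries[1].payload["topic"] == "review_regimen"


def test_empty_confirmed_set_yields_empty_plan(drugref, kb):
    schedule = make_schedule(row_for(drugref, "01000211"))
    confirmed = resolve(build_question_set([], kb), [], kb)
    assert plan(confirmed, schedule, drugref, kb).entries == ()


def test_plan_is_deterministic(drugref, kb):
    scenario = reduction_scenarios(drugref)[0]
    confirmed = _confirm(
        scenario["schedule"], drugref, kb, [Answer(*scenario["answer"])]
    )
    a = plan(confirmed, scenario["schedule"], drugref, kb)
    b = plan(confirmed, scenario["schedule"], drugref, kb)
    assert a == b


@pytest.mark.parametrize("scenario_index", range(6))
def test_applying_top_suggestion_removes_triggering_finding(
    scenario_index, drugref, kb
):
    """End-to-end reduction: detect -> confirm -> plan -> apply -> re-detect."""
    scenario = reduction_scenarios(drugref)[scenario_index]
    schedule = scenario["schedule"]
    before = {f.factor_id for f in detect(schedule, drugref, kb)}
    assert scenario["factor"] in before
    confirmed = _confirm(schedule, drugref, kb, [Answer(*scenario["answer"])])
    assert scenario["factor"] in confirmed.factor_ids
    result = plan(confirmed, schedule, drugref, kb)
    algo_entries = [
        e
        for e in result.entries
        if e.factor_id == scenario["factor"] and e.measure_type == "algorithm"
    ]
    assert algo_entries, "confirmed factor should carry an algorithm measure"
    suggestions = algo_entries[0].payload["suggestions"]
    assert suggestions and suggestions[0]["pzn"] == scenario["expected_pzn"]
    after_schedule = scenario["apply"](schedule, suggestions[0]["pzn"])
    after = {f.factor_id for f in detect(after_schedule, drugref, kb)}
    assert scenario["factor"] not in after
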