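"""Detection rules: PZN, dosage-scheme, schedule-level and keyword families."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medcomplex.detection import (
    DetectionConfig,
    apply_keyword_rules,
    apply_pzn_rules,
    apply_scheme_rules,
    apply_schedule_rules,
    detect,
    match_keywords,
    validate_lexicon,
)

from .conftest import make_row, make_schedule, row_for

MEAL_KEYWORDS = ("meal", "food", "eat", "breakfast", "lunch", "dinner")


# ---------------------------------------------------------------------------
# keyword matching
# ---------------------------------------------------------------------------


def test_lexicon_covers_every_keyword_factor(lexicon, kb):
    assert validate_lexicon(lexicon, kb) == []


@pytest.mark.parametrize("keyword", MEAL_KEYWORDS)
def test_each_meal_keyword_triggers_meal_factor(keyword, lexicon, kb):
    row = make_row(instructions=f"take together with {keyword} please")
    findings = apply_keyword_rules(0, row, lexicon, kb)
    assert any(f.factor_id == "meal_dependent" for f in findings)


def test_meal_keyword_matching_is_case_insensitive(lexicon, kb):
    row = make_row(instructions="Breakfast only")
    findings = apply_keyword_rules(0, row, lexicon, kb)
    assert [f.factor_id for f in findings] == ["meal_dependent"]
    assert ("breakfast", "instructions") in findings[0].evidence.as_dict()["matches"]


@pytest.mark.parametrize("text", ["seafood platter", "beat the eggs", "mealy texture"])
def test_embedded_substrings_do_not_match(text):
    assert match_keywords(text, MEAL_KEYWORDS) == []


def test_word_boundary_and_span_reporting():
    hits = match_keywords("with food", ("food",))
    assert hits == [("food", (5, 9))]
    assert match_keywords("seafood platter", ("food",)) == []
    assert match_keywords("", ("food",)) == []


def test_multiword_phrase_matches_across_spaces():
    assert match_keywords("drink a full  glass of water", ("full glass of water",))


@settings(max_examples=200, derandomize=True)
@given(
    st.sampled_from(MEAL_KEYWORDS),
    st.text(alphabet=st.characters(codec="ascii"), max_size=20),
)
def test_appending_text_never_removes_a_keyword_hit(keyword, suffix):
    base = f"use with {keyword}"
    before = match_keywords(base, MEAL_KEYWORDS)
    after = match_keywords(base + " " + suffix, MEAL_KEYWORDS)
    assert set(before) <= set(after)


def test_prn_fires_on_flag_or_phrase(lexicon, kb):
    flagged = apply_keyword_rules(0, make_row(prn=True), lexicon, kb)
    assert [f.factor_id for f in flagged] == ["prn"]
    worded = apply_keyword_rules(0, make_row(instructions="only if necessary"), lexicon, kb)
    assert [f.factor_id for f in worded] == ["prn"]


# ---------------------------------------------------------------------------
# scheme rules against a brute-force oracle
# ---------------------------------------------------------------------------

COMPANION_SLOTS = (1.0, 0.0, 1.0, 0.0)


def brute_force_scheme_factors(slots):
    """Independent re-statement of the seven scheme rules for a solid-oral
    row next to a fixed 1-0-1-0 companion row."""
    expected = set()
    if any(s > 0 and s != int(s) for s in slots):
        expected.add("tablet_splitting")
    if len([s for s in slots if s > 0]) > 2:
        expected.add("more_than_twice_daily")
    if slots[1] > 0:
        expected.add("lunch_time")
    if any(s >= 2 for s in slots):
        expected.add("multiple_doses_concurrently")
    if len({s for s in slots if s > 0}) >= 2:
        expected.add("different_doses_same_day")
    if any(s > 0 and c == 0 for s, c in zip(slots, COMPANION_SLOTS)):
        expected.add("single_drug_at_timepoint")
    return expected


def test_scheme_rules_match_brute_force_on_all_625_half_unit_schemes(drugref, kb):
    values = (0.0, 0.5, 1.0, 1.5, 2.0)
    companion = row_for(drugref, "01000212", scheme_text="1-0-1-0")
    for slots in itertools.product(values, repeat=4):
        scheme_text = "-".join(f"{s:g}" for s in slots)
        row = row_for(drugref, "04773415", scheme_text=scheme_text)
        schedule = make_schedule(row, companion)
        record = drugref.lookup(row.pzn)
        got = {f.factor_id for f in apply_scheme_rules(0, row, record, schedule, kb)}
        assert got == brute_force_scheme_factors(slots), f"scheme {scheme_text}"


def test_variable_dosing_fires_only_for_non_prn_free_text(drugref, kb):
    record = drugref.lookup("01000212")
    free = row_for(drugref, "01000212", scheme_text="according to plan")
    prn = row_for(drugref, "01000212", scheme_text="according to plan", prn=True)
    schedule = make_schedule(free)
    assert [f.factor_id for f in apply_scheme_rules(0, free, record, schedule, kb)] == [
        "variable_dosing"
    ]
    assert apply_scheme_rules(0, prn, record, make_schedule(prn), kb) == []


def test_lone_drug_rule_needs_two_structured_rows(drugref, kb):
    row = row_for(drugref, "01000212", scheme_text="1-0-0-0")
    record = drugref.lookup(row.pzn)
    assert apply_scheme_rules(0, row, record, make_schedule(row), kb) == []


# ---------------------------------------------------------------------------
# PZN rules
# ---------------------------------------------------------------------------


def test_form_class_maps_to_dosage_form_factor(drugref, kb, lexicon):
    row = row_for(drugref, "01000111")  # transdermal patch
    findings = apply_pzn_rules(0, row, drugref.lookup(row.pzn), kb, lexicon)
    assert [f.factor_id for f in findings] == ["transdermal_patches"]
    assert findings[0].evidence.as_dict()["attribute"] == "form_class"


def test_device_subtype_carried_on_inhaler_finding(drugref, kb, lexicon):
    row = row_for(drugref, "01000072")  # Elpenhaler
    findings = apply_pzn_rules(0, row, drugref.lookup(row.pzn), kb, lexicon)
    assert findings[0].factor_id == "inhalers"
    assert findings[0].device_subtype == "elpenhaler"


def test_nasal_factor_gated_on_prescription_only(drugref, kb, lexicon):
    rx = row_for(drugref, "01000091")
    otc = row_for(drugref, "01000092")
    assert [f.factor_id for f in apply_pzn_rules(0, rx, drugref.lookup(rx.pzn), kb, lexicon)] == [
        "nasal_rx"
    ]
    assert apply_pzn_rules(0, otc, drugref.lookup(otc.pzn), kb, lexicon) == []


def test_injection_factor_split_by_device_subtype(drugref, kb, lexicon):
    vial = row_for(drugref, "01000051")
    pen = row_for(drugref, "01000052")
    assert apply_pzn_rules(0, vial, drugref.lookup(vial.pzn), kb, lexicon)[0].factor_id == (
        "injection_non_prefilled"
    )
    assert apply_pzn_rules(0, pen, drugref.lookup(pen.pzn), kb, lexicon)[0].factor_id == (
        "injection_prefilled"
    )


def test_palatability_flag_requires_liquid_oral_class(drugref, kb, lexicon):
    liquid = row_for(drugref, "01000171")
    found = {f.factor_id for f in apply_pzn_rules(0, liquid, drugref.lookup(liquid.pzn), kb, lexicon)}
    assert found == {"liquid_oral", "unfriendly_liquid_oral"}


def test_measurement_factor_needs_both_product_link_and_keyword(drugref, kb, lexicon):
    record = drugref.lookup("01000191")  # warfarin, self-measurement linked
    with_hit = row_for(drugref, "01000191", instructions="adjust dose according to INR")
    without = row_for(drugref, "01000191", instructions="take in the evening")
    hits = apply_pzn_rules(0, with_hit, record, kb, lexicon)
    assert [f.factor_id for f in hits] == ["complex_measurements"]
    assert hits[0].evidence.kind == "pzn_keyword"
    assert apply_pzn_rules(0, without, record, kb, lexicon) == []


# ---------------------------------------------------------------------------
# schedule-level rules and the combined detector
# ---------------------------------------------------------------------------


def test_polypharmacy_threshold_comparison(drugref, kb):
    pool = ["01000211", "01000212", "01000213", "01000214", "01000215"]
    rows = [row_for(drugref, p) for p in pool]
    config = DetectionConfig(polypharmacy_threshold=5)
    at = apply_schedule_rules(make_schedule(*rows), drugref, kb, config)
    assert [f.factor_id for f in at] == ["total_number_of_drugs"]
    assert at[0].evidence.as_dict()["count"] == 5
    below = apply_schedule_rules(make_schedule(*rows[:4]), drugref, kb, config)
    assert below == []


def test_same_ingredient_different_preparations_pairing(drugref, kb, config):
    a = row_for(drugref, "01000201")
    b = row_for(drugref, "01000202")
    findings = apply_schedule_rules(make_schedule(a, b), drugref, kb, config)
    assert [f.factor_id for f in findings] == ["same_ingredient_different_preparations"]
    assert findings[0].row_indices == (0, 1)
    assert findings[0].evidence.as_dict()["ingredient"] == "paracetamol"


def test_clean_single_row_schedule_has_no_findings(drugref, kb):
    schedule = make_schedule(row_for(drugref, "01000211", scheme_text="1-0-0-0"))
    assert detect(schedule, drugref, kb) == []


def test_one_finding_per_mechanism_fixture(drugref, kb):
    schedule = make_schedule(
        row_for(drugref, "01000111"),  # PZN: transdermal patch
        row_for(drugref, "04773415", scheme_text="0.5-0-0.5-0"),  # scheme: splitting
        row_for(drugref, "01000211", instructions="take with breakfast"),  # keyword
        row_for(drugref, "01000212"),
        row_for(drugref, "01000213"),
    )
    findings = detect(schedule, drugref, kb)
    assert {(f.factor_id, f.evidence.kind) for f in findings} == {
        ("total_number_of_drugs", "line_count"),
        ("transdermal_patches", "pzn_attribute"),
        ("tablet_splitting", "slot_pattern"),
        ("meal_dependent", "matched_keyword"),
    }


def test_detect_is_deterministic(drugref, kb):
    schedule = make_schedule(
        row_for(drugref, "01000071"),
        row_for(drugref, "01000021", scheme_text="1-1-1-0"),
        row_for(drugref, "01000211", instructions="crush the tablet before use"),
    )
    first = detect(schedule, drugref, kb)
    second = detect(schedule, drugref, kb)
    assert first == second


def test_unknown_pzn_skips_pzn_rules_with_warning(drugref, kb):
    schedule = make_schedule(
        make_row(pzn="77777777", brand_name="Mystery", scheme_text="1-0-1-0")
    )
    warnings = []
    findings = detect(schedule, drugref, kb, warnings=warnings)
    assert findings == []
    assert warnings and "77777777" in warnings[0]


def test_empty_schedule_is_rejected(drugref, kb):
    with pytest.raises(ValueError, match="empty schedule"):
        detect(make_schedule(), drugref, kb)
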