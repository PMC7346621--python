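import pytest

from medcomplex import (
    DetectionConfig,
    MedicationRow,
    MedicationSchedule,
    load_drug_reference,
    load_knowledge_base,
    load_lexicon,
    parse_dosage_scheme,
)


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture(scope="session")
def drugref():
    return load_drug_reference()


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon(language="en")


@pytest.fixture(scope="session")
def config():
    return DetectionConfig()


def make_row(**kwargs) -> MedicationRow:
    """Row builder: parses the scheme text and fills sensible defaults."""
    scheme_text = kwargs.pop("scheme_text", "")
    defaults = dict(
        pzn="",
        brand_name="TestDrug",
        active_ingredient="",
        dosage_form="tablet",
        strength="",
        unit="unit",
        instructions="",
        indication="",
        prn=False,
    )
    defaults.update(kwargs)
    return MedicationRow(
        scheme_text=scheme_text, scheme=parse_dosage_scheme(scheme_text), **defaults
    )


def make_schedule(*rows, patient="t") -> MedicationSchedule:
    return MedicationSchedule(rows=tuple(rows), patient_ref=patient)


def replace_rows(schedule, mapping, drop=()):
    """Test-only helper applying a suggestion: the tool itself never mutates
    a schedule. ``mapping`` maps row index -> replacement row."""
    rows = [
        mapping.get(i, row)
        for i, row in enumerate(schedule.rows)
        if i not in drop
    ]
    extra = [row for i, row in mapping.items() if i >= len(schedule.rows)]
    return MedicationSchedule(
        rows=tuple(rows + extra), patient_ref=schedule.patient_ref, issued_on=schedule.issued_on
    )


def reduction_scenarios(drugref):
    """One fixture scenario per substitution algorithm (plus the second
    strength case): schedule, triggering factor, problem-positive answer,
    and how the top suggestion would be applied."""

    def swap(i, scheme_text, instructions=""):
        def apply(schedule, suggestion_pzn):
            new = row_for(drugref, suggestion_pzn, scheme_text=scheme_text, instructions=instructions)
            return replace_rows(schedule, {i: new})

        return apply

    def merge_pair(scheme_text):
        def apply(schedule, suggestion_pzn):
            fdc = row_for(drugref, suggestion_pzn, scheme_text=scheme_text)
            rows = [fdc] + [r for i, r in enumerate(schedule.rows) if i not in (0, 1)]
            return MedicationSchedule(rows=tuple(rows), patient_ref=schedule.patient_ref)

        return apply

    return [
        dict(
            name="split_tablet_to_matching_strength",
            algorithm="alternative_strength",
            factor="tablet_splitting",
            schedule=make_schedule(
                row_for(drugref, "04773415", scheme_text="0.5-0-0.5-0"),
                row_for(drugref, "01000212", scheme_text="1-0-1-0"),
            ),
            answer=("q_tablet_splitting@0", "yes"),
            expected_pzn="04773414",
            apply=swap(0, "1-0-1-0"),
        ),
        dict(
            name="stacked_dose_to_matching_strength",
            algorithm="alternative_strength",
            factor="multiple_doses_concurrently",
            schedule=make_schedule(
                row_for(drugref, "01000011", scheme_text="2-0-0-0"),
                row_for(drugref, "01000212", scheme_text="1-0-0-0"),
            ),
            answer=("q_multiple_concurrent@0", "yes"),
            expected_pzn="01000012",
            apply=swap(0, "1-0-0-0"),
        ),
        dict(
            name="crushed_tablet_to_liquid_form",
            algorithm="alternative_form",
            factor="crushing_tablets",
            schedule=make_schedule(
                row_for(
                    drugref, "01000031", scheme_text="1-0-1-0",
                    instructions="crush the tablet before use",
                ),
                row_for(drugref, "01000212", scheme_text="1-0-1-0"),
            ),
            answer=("q_crushing@0", "yes"),
            expected_pzn="01000032",
            apply=swap(0, "1-0-1-0"),
        ),
        dict(
            name="thrice_daily_to_extended_release",
            algorithm="frequency_reduction",
            factor="more_than_twice_daily",
            schedule=make_schedule(
                row_for(drugref, "01000021", scheme_text="1-1-1-0"),
                row_for(drugref, "01000212", scheme_text="1-0-1-0"),
            ),
            answer=("q_more_than_twice@0", "yes"),
            expected_pzn="01000022",
            apply=swap(0, "1-0-0-0"),
        ),
        dict(
            name="two_antihypertensives_to_fixed_dose_combination",
            algorithm="combination_product",
            factor="total_number_of_drugs",
            schedule=make_schedule(
                row_for(drugref, "01000061", scheme_text="1-0-0-0"),
                row_for(drugref, "01000062", scheme_text="1-0-0-0"),
                row_for(drugref, "01000211", scheme_text="1-0-0-0"),
                row_for(drugref, "01000212", scheme_text="1-0-0-0"),
                row_for(drugref, "01000213", scheme_text="1-0-0-0"),
            ),
            answer=("q_total_number", "yes"),
            expected_pzn="01000063",
            apply=merge_pair("1-0-0-0"),
        ),
        dict(
            name="vial_to_prefilled_injector",
            algorithm="prefilled_device",
            factor="injection_non_prefilled",
            schedule=make_schedule(row_for(drugref, "01000051", scheme_text="1-0-1-0")),
            answer=("q_injection_site_np@0", 5),
            expected_pzn="01000052",
            apply=swap(0, "1-0-1-0"),
        ),
    ]


def row_for(drugref, pzn, scheme_text="1-0-1-0", **kwargs) -> MedicationRow:
    """Row backed by a fixture drug-reference product."""
    rec = drugref.lookup(pzn)
    assert rec is not None, f"fixture PZN {pzn} missing"
    defaults = dict(
        pzn=rec.pzn,
        brand_name=rec.brand_name,
        active_ingredient="+".join(rec.active_ingredients),
        dosage_form=rec.form_class.replace("_", " "),
        strength=f"{rec.strength_mg:g} mg" if rec.strength_mg else "",
    )
    defaults.update(kwargs)
    return make_row(scheme_text=scheme_text, **defaults)
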