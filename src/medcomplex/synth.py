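"""Synthetic medication schedules with known injected complexity factors.

The generator builds fictional but dialect-conformant schedules in which
each requested (automated) factor's triggering condition is planted on at
least one row, while background rows are drawn from trigger-free products
with a neutral morning/evening scheme and noise text verified to contain no
lexicon keyword. The returned ground truth lists every condition knowingly
planted — including structural consequences of the assembled slot matrix
(e.g. a planted noon dose that leaves a drug alone at a time point), which
the generator derives from its own construction data, not by running the
detector. Output is fully determined by the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .detection import DetectionConfig
from .drug_reference import DrugReference
from .knowledge_base import KnowledgeBase, load_knowledge_base
from .schedule_io import MedicationRow, MedicationSchedule, parse_dosage_scheme

#: ground truth entry: (factor_id, triggering row indices)
GroundTruth = tuple[str, tuple[int, ...]]


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthSpec:
    seed: int
    inject: tuple[str, ...] = ()
    #: minimum number of rows; injection may require more
    n_rows: Optional[int] = None
    #: probability of an irrelevant free-text phrase on a background row
    background_noise: float = 0.3


# trigger-free solid-oral products for background rows (distinct ingredients)
BACKGROUND_PZNS = (
    "01000211", "01000212", "01000213", "01000214", "01000215",
    "01000216", "01000217", "01000218", "01000219", "01000220",
    "01000221", "01000222", "01000223", "01000224", "01000225",
    "01000226", "01000227", "01000228", "01000229",
)

# verified against the packaged lexicon to contain no keyword phrase
NOISE_PHRASES = (
    "store below 25 degrees",
    "protect from light",
    "keep out of reach of children",
    "swallow whole",
    "do not freeze",
    "note the expiry date",
    "prescribed by your doctor",
)

NEUTRAL_SCHEME = "1-0-1-0"

# dosage-form factors: candidate products per factor (one is drawn per plant)
FORM_PLANTS = {
    "inhalers": ("01000071", "01000072", "01000073", "01000074", "01000075"),
    "injection_non_prefilled": ("01000051",),
    "injection_prefilled": ("01000052",),
    "transdermal_patches": ("01000111",),
    "nasal_rx": ("01000091",),
    "oropharyngeal_solid": ("01000101",),
    "oropharyngeal_liquid": ("01000102",),
    "ophthalmic": ("01000081", "01000082"),
    "rectal": ("01000121",),
    "dermatological_rx": ("01000131",),
    "liquid_oral": ("01000141", "01000142", "01000032"),
    "otological": ("01000151",),
    "vaginal": ("01000161",),
}

# keyword factors: one designated trigger phrase each, chosen so it matches
# exactly its own factor's phrase list and no other entry
KEYWORD_PLANTS = {
    "once_weekly": "take once a week",
    "every_two_days_or_less": "take every other day",
    "fixed_dosing_interval": "take every 12 hours",
    "occasional_episodic": "short course only",
    "meal_dependent": "take with breakfast",
    "crushing_tablets": "crush the tablet before use",
    "disintegrating_tablets": "dissolve in a glass of water",
    "fixed_times_of_day": "always at the same time",
    "advised_liquid": "take with plenty of water",
    "opening_capsules": "open the capsule and sprinkle the contents",
    "increasing_doses": "slowly increase the dose",
    "decreasing_doses": "taper the dose gradually",
}

# dosage-scheme factors planted with a dedicated product + scheme
SCHEME_PLANTS = {
    "tablet_splitting": ("04773415", "0.5-0-0.5-0"),
    "more_than_twice_daily": ("01000021", "1-1-1-0"),
    "multiple_doses_concurrently": ("01000011", "2-0-0-0"),
    "different_doses_same_day": ("01000230", "2-0-1-0"),
}


def _make_row(record, scheme_text: str, instructions: str = "", prn: bool = False) -> MedicationRow:
    strength = f"{record.strength_mg:g} mg" if record.strength_mg else ""
    return MedicationRow(
        pzn=record.pzn,
        brand_name=record.brand_name,
        active_ingredient="+".join(record.active_ingredients),
        dosage_form=record.form_class.replace("_", " "),
        strength=strength,
        scheme_text=scheme_text,
        scheme=parse_dosage_scheme(scheme_text),
        unit="unit",
        instructions=instructions,
        prn=prn,
    )


class _Pool:
    """Draws background products without repeating while any remain."""

    def __init__(self, rng: random.Random, drugref: DrugReference):
        self.rng = rng
        self.drugref = drugref
        self.available = list(BACKGROUND_PZNS)

    def take(self):
        if not self.available:
            self.available = list(BACKGROUND_PZNS)
        pzn = self.available.pop(self.rng.randrange(len(self.available)))
        return self.drugref.lookup(pzn)


def _derived_truths(
    rows: Sequence[MedicationRow], records: Sequence, threshold: int
) -> set[GroundTruth]:
    """Structural ground truth from the generator's own construction data."""
    truths: set[GroundTruth] = set()
    for i, row in enumerate(rows):
        rec = records[i]
        solid = rec is not None and rec.form_class == "solid_oral"
        if row.scheme.structured:
            s = row.scheme.slots
            if solid and any(x > 0 and x != int(x) for x in s):
                truths.add(("tablet_splitting", (i,)))
            if sum(1 for x in s if x > 0) > 2:
                truths.add(("more_than_twice_daily", (i,)))
            if s[1] > 0:
                truths.add(("lunch_time", (i,)))
            if any(x >= 2 for x in s):
                truths.add(("multiple_doses_concurrently", (i,)))
            if len({x for x in s if x > 0}) >= 2:
                truths.add(("different_doses_same_day", (i,)))
        elif row.scheme_text.strip() and not row.prn:
            truths.add(("variable_dosing", (i,)))
    structured = [(i, r.scheme.slots) for i, r in enumerate(rows) if r.scheme.structured]
    if len(structured) >= 2:
        for i, s in structured:
            for j in range(4):
                if s[j] > 0 and all(o[j] == 0 for k, o in structured if k != i):
                    truths.add(("single_drug_at_timepoint", (i,)))
                    break
    if len(rows) >= threshold:
        truths.add(("total_number_of_drugs", ()))
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            pi, pj = rows[i].pzn, rows[j].pzn
            if not pi or not pj or pi == pj:
                continue
            ing_i = set(records[i].active_ingredients) if records[i] else set(rows[i].ingredients())
            ing_j = set(records[j].active_ingredients) if records[j] else set(rows[j].ingredients())
            if ing_i & ing_j:
                truths.add(("same_ingredient_different_preparations", (i, j)))
    return truths


def generate(
    spec: SynthSpec,
    drugref: DrugReference,
    kb: Optional[KnowledgeBase] = None,
    config: Optional[DetectionConfig] = None,
) -> tuple[MedicationSchedule, list[GroundTruth]]:
    """Build one schedule with the requested factors planted.

    Returns the schedule and the sorted ground-truth list of
    ``(factor_id, row_indices)`` entries. Injecting a factor the catalogue
    does not mark as automated raises :class:`SynthError`.
    """
    kb = kb or load_knowledge_base()
    config = config or DetectionConfig()
    rng = random.Random(spec.seed)
    automated = {f.factor_id for f in kb.automated_factors()}
    inject = list(dict.fromkeys(spec.inject))
    unknown = [f for f in inject if f not in automated]
    if unknown:
        raise SynthError(f"cannot inject non-automated factor(s): {unknown}")

    pool = _Pool(rng, drugref)
    rows: list[MedicationRow] = []
    planted: set[GroundTruth] = set()

    def add_row(row: MedicationRow) -> int:
        rows.append(row)
        return len(rows) - 1

    order = {fid: k for k, fid in enumerate(kb.factor_ids)}
    for fid in sorted(inject, key=lambda f: order[f]):
        if fid in FORM_PLANTS:
            record = drugref.lookup(rng.choice(FORM_PLANTS[fid]))
            i = add_row(_make_row(record, NEUTRAL_SCHEME))
            planted.add((fid, (i,)))
        elif fid in KEYWORD_PLANTS:
            record = pool.take()
            i = add_row(_make_row(record, NEUTRAL_SCHEME, instructions=KEYWORD_PLANTS[fid]))
            planted.add((fid, (i,)))
        elif fid in SCHEME_PLANTS:
            pzn, scheme = SCHEME_PLANTS[fid]
            add_row(_make_row(drugref.lookup(pzn), scheme))
        elif fid == "lunch_time":
            add_row(_make_row(pool.take(), "0-1-0-0"))
        elif fid == "variable_dosing":
            add_row(_make_row(pool.take(), "according to plan"))
        elif fid == "single_drug_at_timepoint":
            add_row(_make_row(pool.take(), "0-0-0-1"))
        elif fid == "prn":
            i = add_row(_make_row(pool.take(), "", prn=True))
            planted.add((fid, (i,)))
        elif fid == "unfriendly_liquid_oral":
            record = drugref.lookup("01000171")
            i = add_row(_make_row(record, NEUTRAL_SCHEME))
            planted.add((fid, (i,)))
            planted.add(("liquid_oral", (i,)))  # the form itself is a factor too
        elif fid == "lack_of_training":
            record = drugref.lookup("01000181")
            i = add_row(_make_row(record, NEUTRAL_SCHEME))
            planted.add((fid, (i,)))
        elif fid == "complex_measurements":
            record = drugref.lookup("01000191")
            i = add_row(_make_row(record, NEUTRAL_SCHEME, instructions="adjust dose according to INR"))
            planted.add((fid, (i,)))
        elif fid == "same_ingredient_different_preparations":
            add_row(_make_row(drugref.lookup("01000201"), NEUTRAL_SCHEME))
            add_row(_make_row(drugref.lookup("01000202"), NEUTRAL_SCHEME))
        elif fid == "total_number_of_drugs":
            pass  # handled by padding below
        else:  # pragma: no cover - every automated factor has a plant
            raise SynthError(f"no plant defined for factor {fid!r}")

    target = len(rows)
    if spec.n_rows is not None:
        target = max(target, spec.n_rows)
    if "total_number_of_drugs" in inject:
        target = max(target, config.polypharmacy_threshold)
    if "single_drug_at_timepoint" in inject:
        target = max(target, 2)
    target = max(target, 1)
    while len(rows) < target:
        record = pool.take()
        noise = rng.choice(NOISE_PHRASES) if rng.random() < spec.background_noise else ""
        add_row(_make_row(record, NEUTRAL_SCHEME, instructions=noise))

    records = [drugref.lookup(r.pzn) for r in rows]
    truth = planted | _derived_truths(rows, records, config.polypharmacy_threshold)
    ordered = sorted(truth, key=lambda t: (t[1][0] if t[1] else -1, order.get(t[0], 999), t[1]))
    schedule = MedicationSchedule(rows=tuple(rows), patient_ref=f"synth-{spec.seed}")
    return schedule, ordered


def generate_suite(
    n_schedules: int = 50,
    seed: int = 0,
    drugref: Optional[DrugReference] = None,
    kb: Optional[KnowledgeBase] = None,
    config: Optional[DetectionConfig] = None,
) -> list[tuple[MedicationSchedule, list[GroundTruth]]]:
    """Regression corpus: schedules whose injections jointly cover all 38
    automated factors (round-robin over the catalogue)."""
    from .drug_reference import load_drug_reference

    drugref = drugref or load_drug_reference()
    kb = kb or load_knowledge_base()
    rng = random.Random(seed)
    automated = [f.factor_id for f in kb.automated_factors()]
    suite = []
    offset = 0
    for k in range(n_schedules):
        count = rng.randint(2, 5)
        inject = tuple(automated[(offset + m) % len(automated)] for m in range(count))
        offset += count
        spec = SynthSpec(seed=rng.randrange(2**31), inject=inject)
        suite.append(generate(spec, drugref, kb, config))
    return suite
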