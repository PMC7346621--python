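"""PZN-keyed drug-reference table.

Supplies the product attributes the PZN-based detection rules and the
substitution algorithms need: dosage-form class, device subtype, strength,
divisibility, palatability, training requirement, linkage to patient
self-measurement, and a curated ``equivalence_group`` that groups
substitutable products of the same ingredient/indication family.

The packaged fixture (``data/drug_reference.csv``) is a small synthetic
table spanning every form class and device subtype, standing in for the
commercial national product database.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .schedule_io import normalize_pzn

logger = logging.getLogger(__name__)

FORM_CLASSES = (
    "inhaler",
    "injection",
    "transdermal_patch",
    "nasal",
    "oropharyngeal_solid",
    "oropharyngeal_liquid",
    "ophthalmic",
    "rectal",
    "dermatological",
    "liquid_oral",
    "otological",
    "vaginal",
    "solid_oral",
    "other",
)
DEVICE_SUBTYPES = (
    "metered_dose_inhaler",
    "elpenhaler",
    "nebuliser",
    "capsule_inhaler",
    "other_inhaler",
    "eye_drops",
    "eye_ointment",
    "liquid_measuring_device",
    "dry_syrup",
    "oral_drops",
    "prefilled_injector",
    "non_prefilled_injector",
)
#: form classes that carry device-specific subtypes
DEVICE_FORM_CLASSES = ("inhaler", "ophthalmic", "liquid_oral", "injection")


@dataclass(frozen=True)
class DrugRecord:
    pzn: str
    brand_name: str
    active_ingredients: tuple[str, ...]
    form_class: str
    device_subtype: Optional[str] = None
    prescription_only: bool = False
    strength_mg: Optional[float] = None
    #: per-ingredient strengths for fixed-dose combinations
    component_strengths_mg: tuple[float, ...] = ()
    divisible: bool = False
    palatability_issue: bool = False
    requires_technique_training: bool = False
    self_measurement_linked: bool = False
    orodispersible: bool = False
    extended_release: bool = False
    equivalence_group: str = ""


@dataclass
class DrugReference:
    """In-memory reference table with PZN and equivalence-group indexes."""

    records: list[DrugRecord]
    _by_pzn: dict[str, DrugRecord] = field(init=False, repr=False)
    _by_group: dict[str, list[DrugRecord]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_pzn = {}
        self._by_group = {}
        for rec in self.records:
            if rec.pzn in self._by_pzn:
                raise ValueError(f"duplicate PZN {rec.pzn!r} in drug reference")
            self._by_pzn[rec.pzn] = rec
            if rec.equivalence_group:
                self._by_group.setdefault(rec.equivalence_group, []).append(rec)

    def lookup(self, pzn: str) -> Optional[DrugRecord]:
        """Exact match on the normalised (zero-padded) PZN; None if unknown."""
        return self._by_pzn.get(normalize_pzn(pzn))

    def group(self, equivalence_group: str) -> list[DrugRecord]:
        return list(self._by_group.get(equivalence_group, []))


def lookup(ref: DrugReference, pzn: str) -> Optional[DrugRecord]:
    return ref.lookup(pzn)


def find_alternatives(
    ref: DrugReference,
    equivalence_group: str,
    *,
    exclude_pzn: str = "",
    form_class: Optional[str] = None,
    form_class_in: Optional[tuple[str, ...]] = None,
    strength_mg: Optional[float] = None,
    device_subtype: Optional[str] = None,
    divisible: Optional[bool] = None,
    orodispersible: Optional[bool] = None,
    extended_release: Optional[bool] = None,
) -> list[DrugRecord]:
    """All group members satisfying every given constraint.

    The query product itself (``exclude_pzn``) is never returned. Results
    are deterministically ordered by strength ascending, then PZN. An
    unknown group yields an empty list with a logged warning.
    """
    members = ref.group(equivalence_group)
    if not members and equivalence_group:
        logger.warning("unknown equivalence group %r", equivalence_group)
        return []
    exclude = normalize_pzn(exclude_pzn)
    out = []
    for rec in members:
        if rec.pzn == exclude:
            continue
        if form_class is not None and rec.form_class != form_class:
            continue
        if form_class_in is not None and rec.form_class not in form_class_in:
            continue
        if strength_mg is not None and (
            rec.strength_mg is None or abs(rec.strength_mg - strength_mg) > 1e-9
        ):
            continue
        if device_subtype is not None and rec.device_subtype != device_subtype:
            continue
        if divisible is not None and rec.divisible != divisible:
            continue
        if orodispersible is not None and rec.orodispersible != orodispersible:
            continue
        if extended_release is not None and rec.extended_release != extended_release:
            continue
        out.append(rec)
    out.sort(key=lambda r: (r.strength_mg if r.strength_mg is not None else float("inf"), r.pzn))
    return out


def _parse_bool(value: str) -> bool:
    return (value or "").strip().lower() in ("true", "1", "yes", "x")


def _parse_record(raw: dict[str, str], index: int) -> DrugRecord:
    pzn = normalize_pzn(raw.get("pzn", ""))
    if not pzn:
        raise ValueError(f"drug reference record {index}: missing PZN")
    form_class = (raw.get("form_class") or "other").strip()
    if form_class not in FORM_CLASSES:
        raise ValueError(f"drug reference record {index} ({pzn}): unknown form_class {form_class!r}")
    subtype = (raw.get("device_subtype") or "").strip() or None
    if subtype is not None:
        if subtype not in DEVICE_SUBTYPES:
            raise ValueError(f"drug reference record {index} ({pzn}): unknown device_subtype {subtype!r}")
        if form_class not in DEVICE_FORM_CLASSES:
            raise ValueError(
                f"drug reference record {index} ({pzn}): device_subtype on non-device form {form_class!r}"
            )
    strength_raw = (raw.get("strength_mg") or "").strip()
    strength = float(strength_raw) if strength_raw else None
    if strength is not None and strength <= 0:
        raise ValueError(f"drug reference record {index} ({pzn}): strength_mg must be positive")
    comp_raw = (raw.get("component_strengths_mg") or "").strip()
    components = tuple(float(x) for x in comp_raw.split("+")) if comp_raw else ()
    ingredients = tuple(
        p.strip().lower() for p in (raw.get("active_ingredients") or "").split("+") if p.strip()
    )
    return DrugRecord(
        pzn=pzn,
        brand_name=(raw.get("brand_name") or "").strip(),
        active_ingredients=ingredients,
        form_class=form_class,
        device_subtype=subtype,
        prescription_only=_parse_bool(raw.get("prescription_only", "")),
        strength_mg=strength,
        component_strengths_mg=components,
        divisible=_parse_bool(raw.get("divisible", "")),
        palatability_issue=_parse_bool(raw.get("palatability_issue", "")),
        requires_technique_training=_parse_bool(raw.get("requires_technique_training", "")),
        self_measurement_linked=_parse_bool(raw.get("self_measurement_linked", "")),
        orodispersible=_parse_bool(raw.get("orodispersible", "")),
        extended_release=_parse_bool(raw.get("extended_release", "")),
        equivalence_group=(raw.get("equivalence_group") or "").strip(),
    )


def default_reference_path() -> Path:
    return Path(str(resources.files("medcomplex").joinpath("data/drug_reference.csv")))


def load_drug_reference(path: Union[str, Path, None] = None) -> DrugReference:
    """Load a drug-reference CSV; ``None`` selects the packaged fixture."""
    ref_path = Path(path) if path is not None else default_reference_path()
    with open(ref_path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        records = [_parse_record(r, i) for i, r in enumerate(reader, start=1)]
    return DrugReference(records=records)
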