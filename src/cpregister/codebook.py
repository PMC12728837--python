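"""Controlled vocabularies parameterising the chronic-pain register pipeline.

A :class:`Codebook` bundles four tables:

* medication classes — which codes are prescription-only analgesics and of
  which analgesic class (opioids, NSAIDs, tricyclics, antiepileptics, ...);
* condition entries — the tiered hierarchy of pain-associated conditions
  (tier 1 triggers the register on coding alone, tier 2 only with at least
  three analgesic prescriptions), cancer-pain codes (never triggering), and
  diagnostic-context codes such as epilepsy that nullify dual-indication
  analgesic classes;
* long-term-condition (LTC) registers — simple code-presence definitions for
  the comparator conditions;
* a consultation cost schedule — one (provider, mode) cell per consultation
  type, costed as rate per minute times mean duration.

The default codebook ships a synthetic vocabulary: 33 named pain-associated
conditions (12 tier 1, 21 tier 2) and 31 comparator LTCs with opaque
placeholder codes. Users studying real extracts substitute their own
SNOMED-CT / EMIS code lists through the same YAML schema; mapping to real
terminologies is deliberately out of scope.
"""

from __future__ import annotations

import logging
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "AnalgesicClass",
    "Provider",
    "Mode",
    "MedicationClassEntry",
    "ConditionEntry",
    "LtcDefinition",
    "CostScheduleEntry",
    "Codebook",
    "CodebookError",
    "load_codebook",
    "write_codebook",
    "default_codebook",
    "resolve_tier",
]


class CodebookError(ValueError):
    """Raised when a codebook violates its schema or invariants."""


class AnalgesicClass(str, Enum):
    simple_analgesic = "simple_analgesic"
    opioid = "opioid"
    nsaid = "nsaid"
    tricyclic = "tricyclic"
    antiepileptic = "antiepileptic"
    other_analgesic = "other_analgesic"
    non_analgesic = "non_analgesic"


class Provider(str, Enum):
    gp = "gp"
    nurse = "nurse"
    other_hcp = "other_hcp"


class Mode(str, Enum):
    face_to_face = "face_to_face"
    telephone = "telephone"
    home_visit = "home_visit"
    digital = "digital"


class MedicationClassEntry(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    medication_code: str
    analgesic_class: AnalgesicClass
    prescription_only: bool = True

    @property
    def countable(self) -> bool:
        """True if issues of this code may count toward the analgesic criterion."""
        return self.prescription_only and self.analgesic_class != AnalgesicClass.non_analgesic


class ConditionEntry(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    condition_code: str
    condition_name: str
    tier: Optional[int] = None
    is_cancer_pain: bool = False
    dual_indication_for: Optional[AnalgesicClass] = None

    @field_validator("tier")
    @classmethod
    def _tier_in_range(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v not in (1, 2):
            raise ValueError(f"tier must be 1 or 2, got {v}")
        return v

    @model_validator(mode="after")
    def _cancer_untiered(self) -> "ConditionEntry":
        if self.is_cancer_pain and self.tier is not None:
            raise ValueError(
                f"cancer-pain code {self.condition_code!r} must not carry a tier"
            )
        if self.tier is not None and self.dual_indication_for is not None:
            raise ValueError(
                f"code {self.condition_code!r} cannot be both tiered and a "
                "dual-indication context code"
            )
        return self


class LtcDefinition(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    ltc_name: str
    condition_codes: frozenset[str]

    @field_validator("condition_codes")
    @classmethod
    def _non_empty(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("condition_codes must be non-empty")
        return v


class CostScheduleEntry(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    provider: Provider
    mode: Mode
    rate_per_minute: float  # GBP per minute of clinician time
    mean_duration: float  # minutes

    @field_validator("rate_per_minute", "mean_duration")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v


class Codebook(BaseModel):
    """Validated bundle of the four vocabulary tables."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    medications: tuple[MedicationClassEntry, ...]
    conditions: tuple[ConditionEntry, ...]
    ltcs: tuple[LtcDefinition, ...]
    cost_schedule: tuple[CostScheduleEntry, ...]

    @model_validator(mode="after")
    def _check_invariants(self) -> "Codebook":
        seen: set[str] = set()
        for m in self.medications:
            if m.medication_code in seen:
                raise ValueError(f"duplicate medication code {m.medication_code!r}")
            seen.add(m.medication_code)
        seen_c: set[str] = set()
        for c in self.conditions:
            if c.condition_code in seen_c:
                raise ValueError(f"duplicate condition code {c.condition_code!r}")
            seen_c.add(c.condition_code)
        tiered = {c.condition_code for c in self.conditions if c.tier is not None}
        seen_l: set[str] = set()
        for ltc in self.ltcs:
            if ltc.ltc_name in seen_l:
                raise ValueError(f"duplicate LTC name {ltc.ltc_name!r}")
            seen_l.add(ltc.ltc_name)
            if ltc.ltc_name != "chronic_pain":
                overlap = ltc.condition_codes & tiered
                if overlap:
                    raise ValueError(
                        f"comparator LTC {ltc.ltc_name!r} uses tiered codes {sorted(overlap)}"
                    )
        cells = {(e.provider, e.mode) for e in self.cost_schedule}
        if len(cells) != len(self.cost_schedule):
            raise ValueError("duplicate (provider, mode) cell in cost schedule")
        expected = {(p, m) for p in Provider for m in Mode}
        missing = expected - cells
        if missing:
            names = sorted(f"{p.value}/{m.value}" for p, m in missing)
            raise ValueError(f"cost schedule missing cells: {names}")
        return self

    # -- lookups -------------------------------------------------------------

    @property
    def tiered_conditions(self) -> tuple[ConditionEntry, ...]:
        return tuple(c for c in self.conditions if c.tier is not None)

    @property
    def tier_map(self) -> dict[str, int]:
        return {c.condition_code: c.tier for c in self.conditions if c.tier is not None}

    @property
    def medication_class_map(self) -> dict[str, AnalgesicClass]:
        return {m.medication_code: m.analgesic_class for m in self.medications}

    @property
    def countable_codes(self) -> frozenset[str]:
        """Medication codes whose issues count toward the analgesic criterion."""
        return frozenset(m.medication_code for m in self.medications if m.countable)

    @property
    def dual_indication_map(self) -> dict[str, AnalgesicClass]:
        """condition_code -> analgesic class it nullifies."""
        return {
            c.condition_code: c.dual_indication_for
            for c in self.conditions
            if c.dual_indication_for is not None
        }

    def ltc(self, name: str) -> LtcDefinition:
        for ltc in self.ltcs:
            if ltc.ltc_name == name:
                return ltc
        available = sorted(l.ltc_name for l in self.ltcs)
        raise KeyError(f"unknown LTC {name!r}; available: {available}")

    def cost_cell(self, provider: str, mode: str) -> CostScheduleEntry:
        for e in self.cost_schedule:
            if e.provider.value == provider and e.mode.value == mode:
                return e
        raise KeyError(f"no cost-schedule cell for provider={provider!r} mode={mode!r}")


_UNKNOWN_TIER_CODES_SEEN: set[str] = set()


def resolve_tier(condition_code: str, codebook: Codebook) -> Optional[int]:
    """Tier of a condition code, or ``None``.

    Cancer-pain codes, diagnostic-context codes, comparator-LTC codes and
    unknown codes all resolve to ``None``; unknown codes are logged once.
    """
    tier = codebook.tier_map.get(condition_code)
    if tier is None:
        known = {c.condition_code for c in codebook.conditions}
        if condition_code not in known and condition_code not in _UNKNOWN_TIER_CODES_SEEN:
            _UNKNOWN_TIER_CODES_SEEN.add(condition_code)
            logger.warning("unknown condition code %r (not in codebook)", condition_code)
    return tier


# ---------------------------------------------------------------------------
# YAML serialisation


def load_codebook(path: str | Path) -> Codebook:
    """Load and validate a codebook from a YAML file.

    The file has four sections: ``medications``, ``conditions``, ``ltcs``,
    ``cost_schedule``. Unknown keys are rejected; any invariant violation
    raises :class:`CodebookError` naming the offending entry.
    """
    path = Path(path)
    if not path.exists():
        raise CodebookError(f"codebook file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CodebookError(f"codebook file {path} is not a mapping")
    try:
        return Codebook.model_validate(raw)
    except (ValidationError, ValueError) as exc:
        raise CodebookError(f"invalid codebook {path}: {exc}") from exc


def write_codebook(codebook: Codebook, path: str | Path) -> Path:
    """Write a codebook to YAML (inverse of :func:`load_codebook`)."""
    path = Path(path)
    data = codebook.model_dump(mode="json")
    # frozensets serialise in arbitrary order; sort for stable round-trips
    for ltc in data["ltcs"]:
        ltc["condition_codes"] = sorted(ltc["condition_codes"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# Default synthetic codebook

_TIER1_CONDITIONS = [
    "fibromyalgia",
    "chronic_low_back_pain",
    "chronic_widespread_pain",
    "complex_regional_pain_syndrome",
    "trigeminal_neuralgia",
    "postherpetic_neuralgia",
    "chronic_migraine",
    "endometriosis",
    "osteoarthritis",
    "rheumatoid_arthritis",
    "sickle_cell_disease",
    "pathological_fracture",
]

_TIER2_CONDITIONS = [
    "gout",
    "ankylosing_spondylitis",
    "psoriatic_arthritis",
    "systemic_lupus_erythematosus",
    "peripheral_neuropathy",
    "diabetic_neuropathy",
    "carpal_tunnel_syndrome",
    "cervical_spondylosis",
    "spinal_stenosis",
    "irritable_bowel_syndrome",
    "chronic_pancreatitis",
    "interstitial_cystitis",
    "chronic_pelvic_pain",
    "temporomandibular_disorder",
    "chronic_tension_headache",
    "osteoporotic_vertebral_collapse",
    "plantar_fasciitis",
    "frozen_shoulder",
    "meralgia_paraesthetica",
    "phantom_limb_pain",
    "chronic_prostatitis",
]

_CANCER_PAIN_CONDITIONS = ["cancer_pain", "malignant_bone_pain"]

# 31 comparator long-term conditions, diagnosis-coded (code presence only).
_COMPARATOR_LTCS = [
    "anxiety",
    "depression",
    "hypertension",
    "asthma",
    "diabetes",
    "coronary_heart_disease",
    "atrial_fibrillation",
    "heart_failure",
    "stroke_tia",
    "peripheral_arterial_disease",
    "chronic_kidney_disease",
    "copd",
    "epilepsy",
    "dementia",
    "parkinsons_disease",
    "multiple_sclerosis",
    "severe_mental_illness",
    "alcohol_dependence",
    "substance_misuse",
    "learning_disability",
    "hypothyroidism",
    "inflammatory_bowel_disease",
    "chronic_liver_disease",
    "cancer",
    "bronchiectasis",
    "psoriasis",
    "glaucoma",
    "hearing_loss",
    "blindness_low_vision",
    "hiv",
    "chronic_fatigue_syndrome",
]

# LTCs whose diagnosis codes nullify a dual-indication analgesic class: an
# antiepileptic issued to a patient with coded epilepsy, or a tricyclic issued
# to a patient with coded depression, is presumed non-analgesic.
_DUAL_INDICATION_LTCS = {
    "epilepsy": AnalgesicClass.antiepileptic,
    "depression": AnalgesicClass.tricyclic,
}

_DEFAULT_MEDICATIONS: list[tuple[str, AnalgesicClass, bool]] = [
    ("MED-SIM-01", AnalgesicClass.simple_analgesic, True),   # co-codamol-like
    ("MED-SIM-02", AnalgesicClass.simple_analgesic, True),
    ("MED-SIM-90", AnalgesicClass.simple_analgesic, False),  # OTC pack, never counted
    ("MED-OPI-01", AnalgesicClass.opioid, True),
    ("MED-OPI-02", AnalgesicClass.opioid, True),
    ("MED-OPI-03", AnalgesicClass.opioid, True),
    ("MED-NSA-01", AnalgesicClass.nsaid, True),
    ("MED-NSA-02", AnalgesicClass.nsaid, True),
    ("MED-TCA-01", AnalgesicClass.tricyclic, True),
    ("MED-TCA-02", AnalgesicClass.tricyclic, True),
    ("MED-AED-01", AnalgesicClass.antiepileptic, True),      # gabapentinoid-like
    ("MED-AED-02", AnalgesicClass.antiepileptic, True),
    ("MED-OTH-01", AnalgesicClass.other_analgesic, True),    # topical agent
    ("MED-NON-01", AnalgesicClass.non_analgesic, True),      # statin-like
    ("MED-NON-02", AnalgesicClass.non_analgesic, True),      # antibiotic-like
]


def default_codebook() -> Codebook:
    """The shipped synthetic codebook.

    33 tiered pain-associated conditions (12 tier 1, 21 tier 2), 2 cancer-pain
    codes, 31 comparator LTCs (one code each, two for the dual-indication
    contexts), 15 medication codes across 7 classes, and a complete 12-cell
    consultation cost schedule with placeholder unit costs. The unit costs are
    deliberately round placeholder values in the style of national
    per-consultation cost benchmarks; substitute published figures for real
    costing work.
    """
    conditions: list[ConditionEntry] = []
    for i, name in enumerate(_TIER1_CONDITIONS, start=1):
        conditions.append(
            ConditionEntry(condition_code=f"CND-T1-{i:02d}", condition_name=name, tier=1)
        )
    for i, name in enumerate(_TIER2_CONDITIONS, start=1):
        conditions.append(
            ConditionEntry(condition_code=f"CND-T2-{i:02d}", condition_name=name, tier=2)
        )
    for i, name in enumerate(_CANCER_PAIN_CONDITIONS, start=1):
        conditions.append(
            ConditionEntry(
                condition_code=f"CND-CA-{i:02d}", condition_name=name, is_cancer_pain=True
            )
        )

    ltcs: list[LtcDefinition] = []
    for i, name in enumerate(_COMPARATOR_LTCS, start=1):
        codes = [f"CND-LTC-{i:02d}"]
        dual = _DUAL_INDICATION_LTCS.get(name)
        conditions.append(
            ConditionEntry(
                condition_code=codes[0], condition_name=name, dual_indication_for=dual
            )
        )
        ltcs.append(LtcDefinition(ltc_name=name, condition_codes=frozenset(codes)))
    # the chronic-pain register itself is algorithmic, but expose its
    # diagnostic code universe as an LTC entry for completeness
    ltcs.append(
        LtcDefinition(
            ltc_name="chronic_pain",
            condition_codes=frozenset(
                f"CND-T1-{i:02d}" for i in range(1, len(_TIER1_CONDITIONS) + 1)
            )
            | frozenset(f"CND-T2-{i:02d}" for i in range(1, len(_TIER2_CONDITIONS) + 1)),
        )
    )

    schedule = [
        CostScheduleEntry(provider=Provider.gp, mode=Mode.face_to_face, rate_per_minute=3.40, mean_duration=9.2),
        CostScheduleEntry(provider=Provider.gp, mode=Mode.telephone, rate_per_minute=3.40, mean_duration=7.1),
        CostScheduleEntry(provider=Provider.gp, mode=Mode.home_visit, rate_per_minute=3.40, mean_duration=13.5),
        CostScheduleEntry(provider=Provider.gp, mode=Mode.digital, rate_per_minute=3.40, mean_duration=5.5),
        CostScheduleEntry(provider=Provider.nurse, mode=Mode.face_to_face, rate_per_minute=0.85, mean_duration=12.0),
        CostScheduleEntry(provider=Provider.nurse, mode=Mode.telephone, rate_per_minute=0.85, mean_duration=7.5),
        CostScheduleEntry(provider=Provider.nurse, mode=Mode.home_visit, rate_per_minute=0.85, mean_duration=18.0),
        CostScheduleEntry(provider=Provider.nurse, mode=Mode.digital, rate_per_minute=0.85, mean_duration=5.0),
        CostScheduleEntry(provider=Provider.other_hcp, mode=Mode.face_to_face, rate_per_minute=1.10, mean_duration=11.0),
        CostScheduleEntry(provider=Provider.other_hcp, mode=Mode.telephone, rate_per_minute=1.10, mean_duration=7.0),
        CostScheduleEntry(provider=Provider.other_hcp, mode=Mode.home_visit, rate_per_minute=1.10, mean_duration=16.0),
        CostScheduleEntry(provider=Provider.other_hcp, mode=Mode.digital, rate_per_minute=1.10, mean_duration=5.5),
    ]

    return Codebook(
        medications=tuple(
            MedicationClassEntry(
                medication_code=c, analgesic_class=k, prescription_only=pom
            )
            for c, k, pom in _DEFAULT_MEDICATIONS
        ),
        conditions=tuple(conditions),
        ltcs=tuple(ltcs),
        cost_schedule=tuple(schedule),
    )
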