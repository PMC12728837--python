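"""Seeded synthetic primary-care populations for pipeline testing.

The generator emulates the statistical structure of an anonymised inner-city
practice extract: demographic marginals typical of a young, multi-ethnic,
deprived urban population; a latent chronic-pain (CP) status drawn from a
logistic model with planted odds ratios on age band, sex, deprivation
quintile, ethnicity, language preference and country of birth; and
prescription / diagnosis / consultation event streams generated conditionally
on that latent status.

Event generation is *constructive*: a CP-positive patient is assigned one of
four realisation pathways (medication-only, tier-1 diagnosis only, tier-2
diagnosis plus analgesics, or both criteria) and receives events guaranteed
to satisfy exactly that pathway's register rules; a CP-negative patient
receives events guaranteed to satisfy none (at most three qualifying
analgesic issues, at most two if a tier-2 code is present, and never a tier-1
code). The register algorithm run on a generated bundle must therefore
recover the latent truth exactly — this is the central oracle for the
register implementation.

Two calibrations keep the headline statistics at their configured targets:

* the logit intercept is solved (by exact enumeration of the independent
  demographic product distribution) so that expected CP prevalence equals
  ``target_prevalence``;
* the consultation mean for patients on no register is solved in closed form
  so the population mean annual consultation count equals ``overall_mean``
  while CP patients keep their configured mean.

Demographic fields are drawn independently of one another (only marginals
are emulated), and missingness in language / country of birth is
missing-completely-at-random.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from .codebook import AnalgesicClass, Codebook, default_codebook
from .cohort import AGE_BANDS, ETHNICITY_LEVELS

__all__ = [
    "SimulationConfig",
    "PopulationBundle",
    "BundleIntegrityError",
    "inner_london_config",
    "simulate_population",
    "calibrate_intercept",
    "calibrate_base_consultation_mean",
    "write_bundle",
    "read_bundle",
]

_BAND_AGE_RANGES = {
    "18-29": (18, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-69": (60, 69),
    "70-79": (70, 79),
    "80-89": (80, 89),
    ">=90": (90, 99),
}

PATHWAYS = ["medication_only", "tier1_only", "tier2_plus", "both"]


def _check_probs(name: str, probs: dict[str, float]) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total!r}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} has a negative probability")


class SimulationConfig(BaseModel):
    """All knobs of the generator; defaults are the 'inner-London-like' preset.

    The preset's marginals, planted odds ratios and utilisation targets mirror
    the published descriptive statistics of an inner-London adult practice
    population (prevalence target 18.6%, CP consultation mean 15.3/year,
    overall mean 6.7/year, anxiety the most prevalent comparator at 21.4%).
    """

    model_config = ConfigDict(extra="forbid")

    n_patients: int = 10_000
    seed: int = 0
    extraction_date: str = "2023-08-31"

    # demographic marginals (independent fields; only marginals are emulated)
    age_band_probs: dict[str, float] = {
        "18-29": 0.24, "30-39": 0.26, "40-49": 0.18, "50-59": 0.13,
        "60-69": 0.09, "70-79": 0.06, "80-89": 0.03, ">=90": 0.01,
    }
    sex_probs: dict[str, float] = {"male": 0.519, "female": 0.481}
    ethnicity_probs: dict[str, float] = {
        "White": 0.539955, "Black Caribbean": 0.063687, "Black African": 0.101530,
        "Asian": 0.081224, "Mixed": 0.054457, "Other": 0.082147, "unknown": 0.077,
    }
    language_probs: dict[str, float] = {
        "English": 0.542685, "non-English": 0.216315, "missing": 0.241,
    }
    country_probs: dict[str, float] = {"UK": 0.244984, "non-UK": 0.297016, "missing": 0.458}

    # latent CP logistic model: odds ratios per non-reference level
    target_prevalence: float = 0.186
    intercept: Optional[float] = None  # None -> calibrated to target_prevalence
    or_age: dict[str, float] = {
        "30-39": 1.67, "40-49": 3.07, "50-59": 5.61, "60-69": 9.32,
        "70-79": 14.58, "80-89": 27.73, ">=90": 39.91,
    }
    or_female: float = 2.22
    or_imd: dict[str, float] = {"2": 1.16, "3": 1.28, "4": 1.56, "5": 1.70}
    or_ethnicity: dict[str, float] = {
        "Black Caribbean": 1.51, "Black African": 1.49, "Asian": 1.16,
        "Mixed": 1.30, "Other": 1.06, "unknown": 0.87,
    }
    or_non_english: float = 0.95
    or_non_uk: float = 0.61

    # register realisation
    criterion_mix: dict[str, float] = {
        "medication_only": 0.35, "tier1_only": 0.25, "tier2_plus": 0.20, "both": 0.20,
    }
    near_miss_rate: float = 0.15  # CP-negatives given a tier-2 code (with <3 analgesics)
    nullified_antiepileptic_rate: float = 0.01  # negatives with epilepsy + antiepileptics
    cancer_code_rate: float = 0.01

    # utilisation
    cp_consult_mean: float = 15.3
    overall_consult_mean: float = 6.7
    consult_dispersion: float = 1.5  # negative-binomial shape k (var = mu + mu^2/k)
    ltc_prevalence: dict[str, float] = {
        "anxiety": 0.214, "depression": 0.150, "hypertension": 0.120, "asthma": 0.117,
    }
    ltc_consult_mean: dict[str, float] = {
        "anxiety": 8.5, "depression": 9.0, "hypertension": 9.5, "asthma": 7.0,
    }
    provider_mix: dict[str, float] = {"gp": 0.72, "nurse": 0.13, "other_hcp": 0.15}
    mode_mix: dict[str, float] = {
        "face_to_face": 0.55, "telephone": 0.33, "home_visit": 0.02, "digital": 0.10,
    }

    # registration structure
    dissent_rate: float = 0.026
    discontinuity_rate: float = 0.087  # incomplete 12-month record

    @field_validator("n_patients")
    @classmethod
    def _n_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_patients must be >= 1")
        return v

    @field_validator("consult_dispersion")
    @classmethod
    def _dispersion_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("consult_dispersion must be > 0")
        return v

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        _check_probs("age_band_probs", self.age_band_probs)
        _check_probs("sex_probs", self.sex_probs)
        _check_probs("ethnicity_probs", self.ethnicity_probs)
        _check_probs("language_probs", self.language_probs)
        _check_probs("country_probs", self.country_probs)
        _check_probs("criterion_mix", self.criterion_mix)
        _check_probs("provider_mix", self.provider_mix)
        _check_probs("mode_mix", self.mode_mix)
        if set(self.age_band_probs) != set(AGE_BANDS):
            raise ValueError("age_band_probs must cover exactly the analysis age bands")
        if set(self.ethnicity_probs) != set(ETHNICITY_LEVELS):
            raise ValueError("ethnicity_probs must cover the grouped ethnicity levels")
        if set(self.criterion_mix) != set(PATHWAYS):
            raise ValueError(f"criterion_mix must cover {PATHWAYS}")
        for name in self.ltc_prevalence:
            if name not in self.ltc_consult_mean:
                raise ValueError(f"ltc_consult_mean missing entry for {name!r}")
            if self.ltc_consult_mean[name] > self.cp_consult_mean:
                raise ValueError(
                    "comparator consultation means must not exceed the CP mean "
                    f"({name!r}: {self.ltc_consult_mean[name]} > {self.cp_consult_mean})"
                )
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        return self


def inner_london_config(n_patients: int = 100_000, seed: int = 0,
                        **overrides) -> SimulationConfig:
    """The shipped inner-London-like preset at a chosen size and seed."""
    return SimulationConfig(n_patients=n_patients, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Calibration


def _logit_eta_components(config: SimulationConfig):
    """Per-covariate (levels, probs, log-ORs) for exact enumeration.

    Language and country enumerate their *latent* two-level distributions
    (missingness is applied after the draw and is MCAR, so the latent
    conditional distribution equals the observed one).
    """
    def latent(probs: dict[str, float]) -> dict[str, float]:
        known = {k: v for k, v in probs.items() if k != "missing"}
        z = sum(known.values())
        return {k: v / z for k, v in known.items()}

    lang = latent(config.language_probs)
    ctry = latent(config.country_probs)
    comps = [
        (
            list(config.age_band_probs),
            list(config.age_band_probs.values()),
            [math.log(config.or_age.get(b, 1.0)) for b in config.age_band_probs],
        ),
        (
            list(config.sex_probs),
            list(config.sex_probs.values()),
            [math.log(config.or_female) if s == "female" else 0.0 for s in config.sex_probs],
        ),
        (
            [str(q) for q in range(1, 6)],
            [0.2] * 5,
            [math.log(config.or_imd.get(str(q), 1.0)) for q in range(1, 6)],
        ),
        (
            list(config.ethnicity_probs),
            list(config.ethnicity_probs.values()),
            [math.log(config.or_ethnicity.get(e, 1.0)) for e in config.ethnicity_probs],
        ),
        (
            list(lang),
            list(lang.values()),
            [math.log(config.or_non_english) if l == "non-English" else 0.0 for l in lang],
        ),
        (
            list(ctry),
            list(ctry.values()),
            [math.log(config.or_non_uk) if c == "non-UK" else 0.0 for c in ctry],
        ),
    ]
    return comps


def calibrate_intercept(config: SimulationConfig) -> float:
    """Intercept making expected prevalence equal ``target_prevalence``.

    The demographic fields are independent, so the expectation
    E[expit(b0 + eta)] is computed exactly by enumerating the product
    distribution of the six covariates and solved for b0 by bisection.
    """
    if config.intercept is not None:
        return config.intercept
    comps = _logit_eta_components(config)
    probs = np.array([1.0])
    etas = np.array([0.0])
    for _, p, lor in comps:
        probs = np.multiply.outer(probs, np.asarray(p)).ravel()
        etas = np.add.outer(etas, np.asarray(lor)).ravel()

    def gap(b0: float) -> float:
        return float(np.dot(probs, expit(b0 + etas))) - config.target_prevalence

    return brentq(gap, -30.0, 30.0, xtol=1e-12)


def calibrate_base_consultation_mean(config: SimulationConfig) -> float:
    """Consultation mean for patients on no register.

    A patient's annual consultation mean is the maximum of the means of the
    registers they belong to, or the base mean if on none. With CP and the
    comparator LTCs planted independently, the expectation of that maximum has
    a closed form; solving it for the base mean pins the overall population
    mean at ``overall_consult_mean``.
    """
    registers = [(config.cp_consult_mean, config.target_prevalence)] + [
        (config.ltc_consult_mean[name], q) for name, q in config.ltc_prevalence.items()
    ]
    registers.sort(key=lambda t: -t[0])
    p_none = 1.0
    expected = 0.0
    for mean, q in registers:
        expected += p_none * q * mean
        p_none *= 1.0 - q
    base = (config.overall_consult_mean - expected) / p_none
    if base <= 0:
        raise ValueError(
            "overall_consult_mean is too low for the configured register means "
            f"(implied base mean {base:.3f} <= 0)"
        )
    return base


# ---------------------------------------------------------------------------
# Bundle container and IO


class BundleIntegrityError(ValueError):
    """Raised when a bundle violates referential or temporal integrity."""


@dataclass
class PopulationBundle:
    """A simulated extract: patient table, three event tables, latent truth."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    consultations: pd.DataFrame
    truth: pd.DataFrame
    extraction_date: pd.Timestamp

    def validate(self) -> None:
        ids = set(self.patients["patient_id"])
        for name in ("prescriptions", "diagnoses", "consultations"):
            table = getattr(self, name)
            orphans = set(table["patient_id"]) - ids
            if orphans:
                raise BundleIntegrityError(
                    f"{name} reference unknown patients: {sorted(orphans)[:5]}"
                )
            if len(table) and pd.to_datetime(table["date"]).max() > self.extraction_date:
                raise BundleIntegrityError(f"{name} contain events after extraction")
        if set(self.truth["patient_id"]) != ids:
            raise BundleIntegrityError("truth table does not cover exactly the patients")

    def __eq__(self, other: object) -> bool:  # frame-wise equality
        if not isinstance(other, PopulationBundle):
            return NotImplemented
        try:
            for name in ("patients", "prescriptions", "diagnoses", "consultations", "truth"):
                pd.testing.assert_frame_equal(getattr(self, name), getattr(other, name))
        except AssertionError:
            return False
        return self.extraction_date == other.extraction_date


_BUNDLE_FILES = {
    "patients": "patients.csv",
    "prescriptions": "prescriptions.csv",
    "diagnoses": "diagnoses.csv",
    "consultations": "consultations.csv",
    "truth": "truth.csv",
}
_DATE_COLUMNS = {
    "patients": ["birth_date", "registration_start", "registration_end"],
    "prescriptions": ["date"],
    "diagnoses": ["date"],
    "consultations": ["date"],
    "truth": [],
}


def write_bundle(bundle: PopulationBundle, directory: str | Path) -> Path:
    """Write a bundle as five CSV files plus a small JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fname in _BUNDLE_FILES.items():
        df = getattr(bundle, name).copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(directory / fname, index=False)
    meta = {"extraction_date": bundle.extraction_date.strftime("%Y-%m-%d")}
    (directory / "bundle.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_bundle(directory: str | Path) -> PopulationBundle:
    """Read a bundle written by :func:`write_bundle`; validates integrity."""
    directory = Path(directory)
    frames = {}
    for name, fname in _BUNDLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"bundle file missing: {path}")
        df = pd.read_csv(path, dtype={"patient_id": str})
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col])
        frames[name] = df
    meta_path = directory / "bundle.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"bundle file missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    bundle = PopulationBundle(
        extraction_date=pd.Timestamp(meta["extraction_date"]), **frames
    )
    if "cp" in bundle.truth.columns:
        bundle.truth["cp"] = bundle.truth["cp"].astype(bool)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Generation


def _draw(rng: np.random.Generator, levels: list[str], probs: list[float],
          n: int) -> np.ndarray:
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)


def _birth_dates(rng: np.random.Generator, ages: np.ndarray,
                 at: pd.Timestamp) -> pd.Series:
    """Birth dates giving exactly ``ages`` completed years at ``at``."""
    offset = rng.integers(0, 365, size=len(ages))
    anniversary = pd.to_datetime(
        {
            "year": at.year - ages,
            "month": np.full(len(ages), at.month),
            "day": np.full(len(ages), at.day),
        }
    )
    return anniversary - pd.to_timedelta(offset, unit="D")


def _event_days_distinct(rng: np.random.Generator, counts: np.ndarray) -> np.ndarray:
    """Day offsets (0..359) with per-patient distinct dates.

    Each of a patient's k issues lands in its own 30-day slot, so dates are
    distinct by construction (k <= 12) and de-duplication cannot erode a
    planted count below its pathway's threshold.
    """
    total = int(counts.sum())
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    slots = np.arange(total) - starts
    return slots * 30 + rng.integers(0, 30, size=total)


def simulate_population(
    config: SimulationConfig, codebook: Codebook | None = None
) -> PopulationBundle:
    """Generate a population bundle; deterministic given (config, seed)."""
    codebook = codebook or default_codebook()
    at = pd.Timestamp(config.extraction_date).as_unit("ns")
    n = config.n_patients
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_demo, rng_latent, rng_rx, rng_dx, rng_cons, rng_miss = (
        np.random.default_rng(s) for s in streams
    )

    # --- demographics ------------------------------------------------------
    patient_id = np.array([f"P{i:07d}" for i in range(1, n + 1)], dtype=object)
    bands = _draw(rng_demo, list(config.age_band_probs), list(config.age_band_probs.values()), n)
    lo = np.array([_BAND_AGE_RANGES[b][0] for b in bands])
    hi = np.array([_BAND_AGE_RANGES[b][1] for b in bands])
    ages = rng_demo.integers(lo, hi + 1)
    birth = _birth_dates(rng_demo, ages, at)

    sex = _draw(rng_demo, list(config.sex_probs), list(config.sex_probs.values()), n)
    ethnicity = _draw(
        rng_demo, list(config.ethnicity_probs), list(config.ethnicity_probs.values()), n
    )

    def latent_levels(probs: dict[str, float]) -> tuple[list[str], list[float]]:
        known = {k: v for k, v in probs.items() if k != "missing"}
        z = sum(known.values())
        return list(known), [v / z for v in known.values()]

    lang_levels, lang_p = latent_levels(config.language_probs)
    language = _draw(rng_demo, lang_levels, lang_p, n)
    ctry_levels, ctry_p = latent_levels(config.country_probs)
    country = _draw(rng_demo, ctry_levels, ctry_p, n)
    imd_score = np.round(rng_demo.uniform(0, 100, size=n), 4)

    discontinuous = rng_demo.random(n) < config.discontinuity_rate
    reg_days_back = np.where(
        discontinuous,
        rng_demo.integers(0, 365, size=n),  # joined inside the window
        rng_demo.integers(365, 3651, size=n),
    )
    registration_start = at - pd.to_timedelta(reg_days_back, unit="D")
    dissent = rng_demo.random(n) < config.dissent_rate

    # --- latent CP status --------------------------------------------------
    b0 = calibrate_intercept(config)
    eta = np.full(n, b0)
    for band, orr in config.or_age.items():
        eta += np.where(bands == band, math.log(orr), 0.0)
    eta += np.where(sex == "female", math.log(config.or_female), 0.0)
    pop_quintile = np.minimum(imd_score // 20 + 1, 5).astype(int)
    for q, orr in config.or_imd.items():
        eta += np.where(pop_quintile == int(q), math.log(orr), 0.0)
    for level, orr in config.or_ethnicity.items():
        eta += np.where(ethnicity == level, math.log(orr), 0.0)
    eta += np.where(language == "non-English", math.log(config.or_non_english), 0.0)
    eta += np.where(country == "non-UK", math.log(config.or_non_uk), 0.0)
    cp = rng_latent.random(n) < expit(eta)

    pathway = np.full(n, "none", dtype=object)
    pathway[cp] = _draw(
        rng_latent, list(config.criterion_mix), list(config.criterion_mix.values()),
        int(cp.sum()),
    )

    # --- comparator LTC membership (independent of CP) ---------------------
    ltc_member: dict[str, np.ndarray] = {}
    for name, q in config.ltc_prevalence.items():
        ltc_member[name] = rng_latent.random(n) < q

    # --- prescriptions -----------------------------------------------------
    dual_classes = set(codebook.dual_indication_map.values())
    safe_codes = sorted(
        m.medication_code
        for m in codebook.medications
        if m.countable and m.analgesic_class not in dual_classes
    )
    aed_codes = sorted(
        m.medication_code
        for m in codebook.medications
        if m.countable and m.analgesic_class == AnalgesicClass.antiepileptic
    )

    counts = np.zeros(n, dtype=int)
    heavy = (pathway == "medication_only") | (pathway == "both")
    counts[heavy] = 4 + rng_rx.poisson(2.0, size=int(heavy.sum()))
    counts[pathway == "tier1_only"] = rng_rx.integers(
        0, 4, size=int((pathway == "tier1_only").sum())
    )
    counts[pathway == "tier2_plus"] = 3

    neg = ~cp
    u = rng_rx.random(n)
    near_miss = neg & (u < config.near_miss_rate)
    nullified = neg & (u >= config.near_miss_rate) & (
        u < config.near_miss_rate + config.nullified_antiepileptic_rate
    )
    plain_neg = neg & ~near_miss & ~nullified
    counts[near_miss] = rng_rx.integers(0, 3, size=int(near_miss.sum()))
    counts[plain_neg] = rng_rx.choice(
        [0, 1, 2, 3], size=int(plain_neg.sum()), p=[0.55, 0.25, 0.12, 0.08]
    )
    counts = np.minimum(counts, 12)

    rx_pid = np.repeat(patient_id, counts)
    rx_days = _event_days_distinct(rng_rx, counts)
    rx_code = rng_rx.choice(np.asarray(safe_codes, dtype=object), size=len(rx_pid))

    # nullified antiepileptics: 4-6 issues that must NOT count (epilepsy code)
    aed_counts = np.zeros(n, dtype=int)
    aed_counts[nullified] = rng_rx.integers(4, 7, size=int(nullified.sum()))
    aed_pid = np.repeat(patient_id, aed_counts)
    aed_days = _event_days_distinct(rng_rx, aed_counts)
    aed_code = rng_rx.choice(np.asarray(aed_codes, dtype=object), size=len(aed_pid))

    # non-countable background scripts (non-analgesics and OTC packs)
    bg_pool = sorted(
        m.medication_code for m in codebook.medications if not m.countable
    )
    bg_counts = rng_rx.poisson(0.5, size=n)
    bg_pid = np.repeat(patient_id, bg_counts)
    bg_days = rng_rx.integers(0, 365, size=len(bg_pid))
    bg_code = rng_rx.choice(np.asarray(bg_pool, dtype=object), size=len(bg_pid))

    prescriptions = pd.DataFrame(
        {
            "patient_id": np.concatenate([rx_pid, aed_pid, bg_pid]),
            "date": at - pd.to_timedelta(
                np.concatenate([rx_days, aed_days, bg_days]), unit="D"
            ),
            "medication_code": np.concatenate([rx_code, aed_code, bg_code]),
        }
    ).sort_values(["patient_id", "date", "medication_code"], kind="stable").reset_index(drop=True)

    # --- diagnoses ---------------------------------------------------------
    tier1_codes = sorted(c.condition_code for c in codebook.conditions if c.tier == 1)
    tier2_codes = sorted(c.condition_code for c in codebook.conditions if c.tier == 2)
    cancer_codes = sorted(c.condition_code for c in codebook.conditions if c.is_cancer_pain)
    epilepsy_codes = sorted(
        code for code, klass in codebook.dual_indication_map.items()
        if klass == AnalgesicClass.antiepileptic
    )

    dx_pid: list[np.ndarray] = []
    dx_code: list[np.ndarray] = []

    def add_codes(mask: np.ndarray, pool: list[str]) -> None:
        k = int(mask.sum())
        if k == 0 or not pool:
            return
        dx_pid.append(patient_id[mask])
        dx_code.append(rng_dx.choice(np.asarray(pool, dtype=object), size=k))

    add_codes((pathway == "tier1_only") | (pathway == "both"), tier1_codes)
    add_codes((pathway == "tier2_plus") | near_miss, tier2_codes)
    add_codes(nullified, epilepsy_codes)
    add_codes(rng_dx.random(n) < config.cancer_code_rate, cancer_codes)
    for name, member in ltc_member.items():
        add_codes(member, sorted(codebook.ltc(name).condition_codes))

    if dx_pid:
        all_pid = np.concatenate(dx_pid)
        all_code = np.concatenate(dx_code)
    else:  # pragma: no cover - degenerate config
        all_pid = np.array([], dtype=object)
        all_code = np.array([], dtype=object)
    dx_days = rng_dx.integers(0, 1826, size=len(all_pid))
    diagnoses = pd.DataFrame(
        {
            "patient_id": all_pid,
            "date": at - pd.to_timedelta(dx_days, unit="D"),
            "condition_code": all_code,
        }
    ).drop_duplicates().sort_values(
        ["patient_id", "date", "condition_code"], kind="stable"
    ).reset_index(drop=True)

    # --- consultations -----------------------------------------------------
    base_mean = calibrate_base_consultation_mean(config)
    mu = np.full(n, base_mean)
    for name, member in ltc_member.items():
        mu = np.where(member, np.maximum(mu, config.ltc_consult_mean[name]), mu)
    mu = np.where(cp, config.cp_consult_mean, mu)
    k = config.consult_dispersion
    lam = rng_cons.gamma(shape=k, scale=mu / k)
    n_cons = rng_cons.poisson(lam)

    cons_pid = np.repeat(patient_id, n_cons)
    cons_days = rng_cons.integers(0, 365, size=len(cons_pid))
    providers = _draw(
        rng_cons, list(config.provider_mix), list(config.provider_mix.values()), len(cons_pid)
    )
    modes = _draw(rng_cons, list(config.mode_mix), list(config.mode_mix.values()), len(cons_pid))
    cell_mean = np.array(
        [codebook.cost_cell(p, m).mean_duration for p, m in zip(providers, modes)]
    )
    duration = np.round(
        np.maximum(rng_cons.gamma(shape=4.0, scale=cell_mean / 4.0), 1.0), 1
    )
    consultations = pd.DataFrame(
        {
            "patient_id": cons_pid,
            "date": at - pd.to_timedelta(cons_days, unit="D"),
            "provider": providers,
            "mode": modes,
            "duration": duration,
        }
    ).sort_values(["patient_id", "date", "provider", "mode"], kind="stable").reset_index(drop=True)

    # --- recorded missingness (MCAR) --------------------------------------
    lang_missing = rng_miss.random(n) < config.language_probs.get("missing", 0.0)
    ctry_missing = rng_miss.random(n) < config.country_probs.get("missing", 0.0)
    language_rec = language.astype(object)
    language_rec[lang_missing] = np.nan
    country_rec = country.astype(object)
    country_rec[ctry_missing] = np.nan

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "birth_date": birth,
            "sex": sex,
            "ethnicity": ethnicity,
            "imd_score": imd_score,
            "language_preference": language_rec,
            "country_of_birth": country_rec,
            "registration_start": registration_start,
            "registration_end": at,
            "dissent": dissent,
        }
    )
    truth = pd.DataFrame({"patient_id": patient_id, "cp": cp, "pathway": pathway})

    bundle = PopulationBundle(
        patients=patients,
        prescriptions=prescriptions,
        diagnoses=diagnoses,
        consultations=consultations,
        truth=truth,
        extraction_date=at,
    )
    bundle.validate()
    return bundle
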