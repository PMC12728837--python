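"""Cohort construction: eligibility rules and analysis covariates.

Eligibility mirrors a registered-adult primary-care extract: age >= 18 in
completed years at the extraction date, a continuous registration covering the
full 12 months ending at extraction, and no informed-dissent flag. Covariates
are the ones the downstream inequality model uses: closed 10-year age bands
(18-29 ... >=90), grouped ethnicity, and within-sample deprivation quintiles
(quintile 1 = least deprived) cut at the 20/40/60/80th percentiles of the
IMD score over the eligible cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BANDS",
    "ETHNICITY_LEVELS",
    "ExclusionLog",
    "apply_eligibility",
    "derive_age_bands",
    "age_band_of",
    "assign_imd_quintiles",
    "build_cohort",
]

# Closed decade bands; the last is open-ended.
AGE_BANDS = ["18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89", ">=90"]
_BAND_EDGES = np.array([18, 30, 40, 50, 60, 70, 80, 90])

ETHNICITY_LEVELS = [
    "White",
    "Black Caribbean",
    "Black African",
    "Asian",
    "Mixed",
    "Other",
    "unknown",
]

# 12-month analysis window length in days; the window is the half-open
# interval (extraction_date - WINDOW_DAYS, extraction_date].
WINDOW_DAYS = 365


@dataclass
class ExclusionLog:
    """Counts of patients removed at eligibility, by reason."""

    under_18: int = 0
    incomplete_record: int = 0
    dissent: int = 0
    missing_birth_date: int = 0

    @property
    def total(self) -> int:
        return self.under_18 + self.incomplete_record + self.dissent + self.missing_birth_date

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["under_18", "incomplete_record", "dissent", "missing_birth_date"],
                "n_excluded": [
                    self.under_18,
                    self.incomplete_record,
                    self.dissent,
                    self.missing_birth_date,
                ],
            }
        )


def _completed_years(birth: pd.Series, at: pd.Timestamp) -> pd.Series:
    """Age in completed years at ``at`` (registry convention)."""
    birth = pd.to_datetime(birth)
    had_birthday = (birth.dt.month < at.month) | (
        (birth.dt.month == at.month) & (birth.dt.day <= at.day)
    )
    return at.year - birth.dt.year - (~had_birthday).astype(int)


def apply_eligibility(
    patients: pd.DataFrame, extraction_date: str | pd.Timestamp
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the study eligibility rules.

    Keeps patients aged >= 18 at ``extraction_date`` whose registration covers
    the whole 12-month window ending at extraction and who have not recorded
    informed dissent. Exclusions are applied in a fixed order (missing birth
    date, dissent, age, record continuity) and each patient is counted once
    under the first reason that fires.

    Returns the eligible subset (with an ``age_years`` column added) and an
    :class:`ExclusionLog`.
    """
    at = pd.Timestamp(extraction_date)
    log = ExclusionLog()
    df = patients.copy()

    missing_bd = pd.to_datetime(df["birth_date"], errors="coerce").isna()
    log.missing_birth_date = int(missing_bd.sum())
    df = df[~missing_bd]

    dissent = df["dissent"].astype(bool)
    log.dissent = int(dissent.sum())
    df = df[~dissent]

    age = _completed_years(df["birth_date"], at)
    under = age < 18
    log.under_18 = int(under.sum())
    df = df[~under]
    age = age[~under]

    window_start = at - pd.Timedelta(days=WINDOW_DAYS)
    covered = (pd.to_datetime(df["registration_start"]) <= window_start) & (
        pd.to_datetime(df["registration_end"]) >= at
    )
    log.incomplete_record = int((~covered).sum())
    df = df[covered]

    out = df.copy()
    out["age_years"] = age[covered].astype(int)
    return out.reset_index(drop=True), log


def age_band_of(age_years: int) -> str:
    """Band label for a single age (>= 18)."""
    idx = int(np.searchsorted(_BAND_EDGES, age_years, side="right")) - 1
    return AGE_BANDS[idx]


def derive_age_bands(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add an ``age_band`` categorical from ``age_years``."""
    idx = np.searchsorted(_BAND_EDGES, cohort["age_years"].to_numpy(), side="right") - 1
    out = cohort.copy()
    out["age_band"] = pd.Categorical(
        np.asarray(AGE_BANDS, dtype=object)[idx], categories=AGE_BANDS, ordered=True
    )
    return out


def assign_imd_quintiles(cohort: pd.DataFrame) -> pd.DataFrame:
    """Assign within-cohort deprivation quintiles from ``imd_score``.

    Cut points are the 20/40/60/80th percentiles of the observed scores;
    quintile 1 holds the lowest (least deprived) scores. A score-group tied
    exactly at a cut point goes to the lower quintile, so the assignment is
    deterministic under ties; if every score is identical all patients land in
    quintile 1 and a warning is logged. Missing scores get a missing quintile.
    """
    out = cohort.copy()
    scores = pd.to_numeric(out["imd_score"], errors="coerce")
    observed = scores.dropna()
    if observed.empty:
        logger.warning("all IMD scores missing; quintiles left missing")
        out["imd_quintile"] = pd.array([pd.NA] * len(out), dtype="Int64")
        return out
    if len(observed) < 5:
        raise ValueError(f"need at least 5 IMD scores to form quintiles, got {len(observed)}")
    cuts = np.percentile(observed.to_numpy(), [20, 40, 60, 80])
    if observed.nunique() == 1:
        logger.warning("all IMD scores tied; every patient assigned quintile 1")
    q = 1 + (scores.to_numpy()[:, None] > cuts[None, :]).sum(axis=1)
    out["imd_quintile"] = pd.array(
        [int(v) if ok else pd.NA for v, ok in zip(q, scores.notna())], dtype="Int64"
    )
    return out


def build_cohort(
    patients: pd.DataFrame, extraction_date: str | pd.Timestamp
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Eligibility + covariate derivation in one call.

    Returns the analysis cohort (one row per eligible patient, with
    ``age_years``, ``age_band`` and ``imd_quintile`` derived) and the
    exclusion log. Ethnicity missing values are mapped to the explicit
    ``"unknown"`` level here, since recorded-as-unknown is itself a reported
    analysis level.
    """
    eligible, log = apply_eligibility(patients, extraction_date)
    cohort = derive_age_bands(eligible)
    cohort = assign_imd_quintiles(cohort)
    eth = cohort["ethnicity"].astype(object).where(cohort["ethnicity"].notna(), "unknown")
    cohort["ethnicity_grouped"] = pd.Categorical(eth, categories=ETHNICITY_LEVELS)
    return cohort, log
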