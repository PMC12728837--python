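"""The chronic-pain register algorithm and comparator LTC registers.

A patient enters the chronic-pain (CP) register through either of two routes,
or both:

* **medication criterion** — four or more prescription-only analgesic issues
  in the 12 months before extraction. Tricyclics and antiepileptics count as
  analgesics only for patients without the corresponding dual-indication
  diagnosis (e.g. an epilepsy code nullifies antiepileptic counting) at any
  date up to extraction.
* **diagnostic criterion** — any tier-1 condition code ever recorded (these
  conditions are strongly enough associated with pain to qualify without
  analgesic evidence); or any tier-2 code together with at least three
  qualifying analgesic issues in the same 12-month window. Cancer-pain codes
  never trigger the register.

Comparator long-term-condition registers are simple code-presence registers:
one qualifying diagnosis code at any date up to extraction.

Counting conventions: one prescription event is one issue, with exact
duplicates (same patient, date and code) collapsed; diagnosis lookback is
lifetime while analgesic counting is windowed to 12 months.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .codebook import Codebook
from .cohort import WINDOW_DAYS

logger = logging.getLogger(__name__)

__all__ = [
    "MEDICATION_THRESHOLD",
    "TIER2_ANALGESIC_THRESHOLD",
    "count_analgesic_prescriptions",
    "medication_criterion",
    "diagnostic_criterion",
    "build_cp_register",
    "build_ltc_register",
    "build_all_ltc_registers",
]

MEDICATION_THRESHOLD = 4  # issues needed for the medication criterion
TIER2_ANALGESIC_THRESHOLD = 3  # issues needed alongside a tier-2 code

_REGISTER_COLUMNS = [
    "patient_id",
    "on_register",
    "medication_criterion",
    "diagnostic_criterion",
    "analgesic_count",
    "triggering_tier",
]


def _nullified_classes(diagnoses: pd.DataFrame, codebook: Codebook,
                       extraction_date: pd.Timestamp) -> pd.DataFrame:
    """(patient_id, analgesic_class) pairs nullified by dual-indication codes."""
    dual = codebook.dual_indication_map
    if diagnoses.empty or not dual:
        return pd.DataFrame(columns=["patient_id", "analgesic_class"])
    d = diagnoses[pd.to_datetime(diagnoses["date"]) <= extraction_date]
    d = d[d["condition_code"].isin(dual)]
    if d.empty:
        return pd.DataFrame(columns=["patient_id", "analgesic_class"])
    out = pd.DataFrame(
        {
            "patient_id": d["patient_id"].to_numpy(),
            "analgesic_class": d["condition_code"].map(
                {k: v.value for k, v in dual.items()}
            ),
        }
    )
    return out.drop_duplicates()


def _analgesic_counts(
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codebook: Codebook,
    extraction_date: pd.Timestamp,
) -> pd.Series:
    """Qualifying analgesic issues per patient in the 12-month window.

    Vectorised over all patients; patients with no qualifying issues are
    absent from the returned Series (count 0 implied).
    """
    if prescriptions.empty:
        return pd.Series(dtype=int)
    rx = prescriptions.copy()
    rx["date"] = pd.to_datetime(rx["date"])
    window_start = extraction_date - pd.Timedelta(days=WINDOW_DAYS)
    rx = rx[(rx["date"] > window_start) & (rx["date"] <= extraction_date)]

    known = set(codebook.medication_class_map)
    unknown = set(rx.loc[~rx["medication_code"].isin(known), "medication_code"])
    if unknown:
        logger.warning("ignoring %d unknown medication codes: %s",
                       len(unknown), sorted(unknown)[:10])
    rx = rx[rx["medication_code"].isin(codebook.countable_codes)]
    # one issue = one (patient, date, code); duplicated extract rows collapse
    rx = rx.drop_duplicates(subset=["patient_id", "date", "medication_code"])
    if rx.empty:
        return pd.Series(dtype=int)

    rx["analgesic_class"] = rx["medication_code"].map(
        {k: v.value for k, v in codebook.medication_class_map.items()}
    )
    nullified = _nullified_classes(diagnoses, codebook, extraction_date)
    if not nullified.empty:
        keyed = rx.merge(
            nullified.assign(_drop=True),
            on=["patient_id", "analgesic_class"],
            how="left",
        )
        rx = keyed[keyed["_drop"].isna()]
    return rx.groupby("patient_id").size()


def count_analgesic_prescriptions(
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    patient_id: str,
    extraction_date: str | pd.Timestamp,
    codebook: Codebook,
) -> int:
    """Qualifying analgesic issues for one patient in the 12-month window."""
    at = pd.Timestamp(extraction_date)
    rx = prescriptions[prescriptions["patient_id"] == patient_id]
    dx = diagnoses[diagnoses["patient_id"] == patient_id]
    counts = _analgesic_counts(rx, dx, codebook, at)
    return int(counts.get(patient_id, 0))


def medication_criterion(analgesic_count: int) -> bool:
    """True iff the windowed analgesic issue count meets the threshold (>=4)."""
    return analgesic_count >= MEDICATION_THRESHOLD


def diagnostic_criterion(
    diagnoses: pd.DataFrame,
    analgesic_count: int,
    patient_id: str,
    codebook: Codebook,
    extraction_date: str | pd.Timestamp,
) -> tuple[bool, int | None]:
    """Evaluate the tiered diagnostic criterion for one patient.

    Returns ``(fired, triggering_tier)``: tier 1 fires on code presence alone;
    tier 2 requires at least three qualifying analgesic issues; cancer-pain
    and untiered codes never fire.
    """
    at = pd.Timestamp(extraction_date)
    dx = diagnoses[
        (diagnoses["patient_id"] == patient_id)
        & (pd.to_datetime(diagnoses["date"]) <= at)
    ]
    tiers = dx["condition_code"].map(codebook.tier_map)
    if (tiers == 1).any():
        return True, 1
    if (tiers == 2).any() and analgesic_count >= TIER2_ANALGESIC_THRESHOLD:
        return True, 2
    return False, None


def build_cp_register(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codebook: Codebook,
    extraction_date: str | pd.Timestamp,
) -> pd.DataFrame:
    """Evaluate the CP register over a whole cohort (vectorised).

    Returns one row per cohort member with columns ``patient_id``,
    ``on_register``, ``medication_criterion``, ``diagnostic_criterion``,
    ``analgesic_count`` and ``triggering_tier`` (1, 2 or <NA>). Events for
    patients outside the cohort are ignored (one summary log line).
    """
    at = pd.Timestamp(extraction_date)
    ids = cohort["patient_id"]
    id_set = set(ids)

    rx = prescriptions[prescriptions["patient_id"].isin(id_set)]
    dx = diagnoses[diagnoses["patient_id"].isin(id_set)]
    n_foreign = (len(prescriptions) - len(rx)) + (len(diagnoses) - len(dx))
    if n_foreign:
        logger.info("ignored %d events for patients outside the cohort", n_foreign)

    counts = _analgesic_counts(rx, dx, codebook, at)
    analgesic_count = ids.map(counts).fillna(0).astype(int)

    dxw = dx[pd.to_datetime(dx["date"]) <= at]
    tier_of = dxw["condition_code"].map(codebook.tier_map)
    has_t1 = set(dxw.loc[tier_of == 1, "patient_id"])
    has_t2 = set(dxw.loc[tier_of == 2, "patient_id"])

    t1 = ids.isin(has_t1).to_numpy()
    t2 = ids.isin(has_t2).to_numpy()
    n_analg = analgesic_count.to_numpy()

    med = n_analg >= MEDICATION_THRESHOLD
    diag = t1 | (t2 & (n_analg >= TIER2_ANALGESIC_THRESHOLD))
    tier = np.where(t1, 1, np.where(t2 & (n_analg >= TIER2_ANALGESIC_THRESHOLD), 2, 0))

    out = pd.DataFrame(
        {
            "patient_id": ids.to_numpy(),
            "on_register": med | diag,
            "medication_criterion": med,
            "diagnostic_criterion": diag,
            "analgesic_count": n_analg,
            "triggering_tier": pd.array(
                [t if t else pd.NA for t in tier], dtype="Int64"
            ),
        },
        columns=_REGISTER_COLUMNS,
    )
    return out


def build_ltc_register(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codebook: Codebook,
    ltc_name: str,
    extraction_date: str | pd.Timestamp,
) -> pd.DataFrame:
    """Code-presence register for one comparator LTC.

    A cohort member is on the register if any code from the LTC's code set
    appears at any date up to extraction. Returns ``patient_id``/``on_register``.
    """
    at = pd.Timestamp(extraction_date)
    definition = codebook.ltc(ltc_name)  # raises KeyError listing names
    dx = diagnoses[
        diagnoses["condition_code"].isin(definition.condition_codes)
        & (pd.to_datetime(diagnoses["date"]) <= at)
    ]
    members = set(dx["patient_id"]) & set(cohort["patient_id"])
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "on_register": cohort["patient_id"].isin(members).to_numpy(),
        }
    )


def build_all_ltc_registers(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codebook: Codebook,
    extraction_date: str | pd.Timestamp,
    ltc_names: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format membership table for several LTC registers.

    Returns columns ``ltc_name``, ``patient_id`` for members only.
    """
    names = ltc_names or [l.ltc_name for l in codebook.ltcs if l.ltc_name != "chronic_pain"]
    frames = []
    for name in names:
        reg = build_ltc_register(cohort, diagnoses, codebook, name, extraction_date)
        members = reg.loc[reg["on_register"], ["patient_id"]].copy()
        members.insert(0, "ltc_name", name)
        frames.append(members)
    if not frames:
        return pd.DataFrame(columns=["ltc_name", "patient_id"])
    return pd.concat(frames, ignore_index=True)
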