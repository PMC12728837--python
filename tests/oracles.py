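"""Independent brute-force oracle for the chronic-pain register rules.

Pure-Python, one patient at a time, reading the rules literally: no shared
code with the vectorised implementation beyond the codebook container.
"""

from __future__ import annotations

import pandas as pd

from cpregister.codebook import AnalgesicClass, Codebook


def brute_force_patient(
    rx: list[tuple[pd.Timestamp, str]],
    dx: list[tuple[pd.Timestamp, str]],
    codebook: Codebook,
    extraction_date: pd.Timestamp,
) -> dict:
    """Evaluate the register rules for one patient from raw event lists."""
    window_start = extraction_date - pd.Timedelta(days=365)

    class_of = {m.medication_code: m.analgesic_class for m in codebook.medications}
    pom = {m.medication_code for m in codebook.medications if m.prescription_only}
    dual = {
        c.condition_code: c.dual_indication_for
        for c in codebook.conditions
        if c.dual_indication_for is not None
    }
    tier_of = {c.condition_code: c.tier for c in codebook.conditions if c.tier is not None}

    lifetime_dx = [(d, c) for d, c in dx if d <= extraction_date]
    nullified: set[AnalgesicClass] = {
        dual[c] for _, c in lifetime_dx if c in dual
    }

    issues = set()  # distinct (date, code) pairs
    for d, code in rx:
        if not (window_start < d <= extraction_date):
            continue
        if code not in class_of or code not in pom:
            continue
        klass = class_of[code]
        if klass == AnalgesicClass.non_analgesic:
            continue
        if klass in nullified:
            continue
        issues.add((d, code))
    count = len(issues)

    medication = count >= 4
    tiers = {tier_of[c] for _, c in lifetime_dx if c in tier_of}
    if 1 in tiers:
        diagnostic, tier = True, 1
    elif 2 in tiers and count >= 3:
        diagnostic, tier = True, 2
    else:
        diagnostic, tier = False, None

    return {
        "on_register": medication or diagnostic,
        "medication_criterion": medication,
        "diagnostic_criterion": diagnostic,
        "analgesic_count": count,
        "triggering_tier": tier,
    }


def brute_force_register(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codebook: Codebook,
    extraction_date: pd.Timestamp,
) -> pd.DataFrame:
    rx_by_patient: dict[str, list] = {}
    for row in prescriptions.itertuples(index=False):
        rx_by_patient.setdefault(row.patient_id, []).append(
            (pd.Timestamp(row.date), row.medication_code)
        )
    dx_by_patient: dict[str, list] = {}
    for row in diagnoses.itertuples(index=False):
        dx_by_patient.setdefault(row.patient_id, []).append(
            (pd.Timestamp(row.date), row.condition_code)
        )
    rows = []
    for pid in cohort["patient_id"]:
        res = brute_force_patient(
            rx_by_patient.get(pid, []), dx_by_patient.get(pid, []), codebook, extraction_date
        )
        rows.append({"patient_id": pid, **res})
    out = pd.DataFrame(rows)
    out["triggering_tier"] = pd.array(out["triggering_tier"], dtype="Int64")
    return out
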