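"""Consultation utilisation and primary-care costing per register.

Utilisation counts *every* consultation of a register member in the 12-month
window — overall contact rates, not pain-specific contacts — stratified over
the twelve provider-by-mode cells (GP / nurse / other healthcare professional
by face-to-face / telephone / home visit / digital). Registers overlap, so a
patient on several registers contributes her consultations to every one of
their summaries.

Costing prices each consultation at its cell's per-minute rate times the
cell's mean duration (or the recorded duration when present and requested).
All accumulation is in integer thousandths of a penny (millipence), so
component costs add up to totals bit-exactly and rescaling a schedule
rescales every output exactly; conversion to pounds happens only at the
reporting edge.

Reporting conventions: rates to one decimal place, per-patient costs to the
nearest pound, the headline excess-cost comparison to an integer percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import Codebook, Mode, Provider
from .cohort import WINDOW_DAYS

logger = logging.getLogger(__name__)

__all__ = [
    "UtilisationSummary",
    "CostSummary",
    "consultation_rate",
    "apply_cost_schedule",
    "cost_summary",
    "excess_cost_percent",
    "prevalence_percent",
    "rank_conditions",
]


def prevalence_percent(n_members: int, n_cohort: int) -> float:
    """Register prevalence as a percentage, to one decimal place."""
    if n_cohort <= 0:
        raise ValueError("cohort size must be positive")
    return round(100 * n_members / n_cohort, 1)

_CELLS = [(p.value, m.value) for p in Provider for m in Mode]


@dataclass(frozen=True)
class UtilisationSummary:
    """Consultation totals and mean annual rate for one register."""

    ltc_name: str
    n_patients: int
    total_consultations: int
    breakdown: dict[tuple[str, str], int]  # (provider, mode) -> count

    @property
    def mean_rate(self) -> float:
        """Consultations per patient per year, to one decimal place."""
        if self.n_patients == 0:
            return 0.0
        return round(self.total_consultations / self.n_patients, 1)


MILLIPENCE_PER_GBP = 100_000  # internal cost unit: 1/1000 of a penny


@dataclass(frozen=True)
class CostSummary:
    """Annual consultation cost for one register, held in integer millipence."""

    ltc_name: str
    n_patients: int
    total_cost_millipence: int
    provider_cost_millipence: dict[str, int]  # gp / nurse / other_hcp components

    @property
    def total_cost_gbp(self) -> float:
        return self.total_cost_millipence / MILLIPENCE_PER_GBP

    def provider_cost_gbp(self, provider: str) -> float:
        return self.provider_cost_millipence[provider] / MILLIPENCE_PER_GBP

    @property
    def per_patient_cost_gbp(self) -> int:
        """Annual cost per register member, rounded to the nearest pound."""
        if self.n_patients == 0:
            return 0
        return int(round(self.total_cost_millipence / self.n_patients / MILLIPENCE_PER_GBP))


def _window_events(
    consultations: pd.DataFrame, extraction_date: pd.Timestamp
) -> pd.DataFrame:
    dates = pd.to_datetime(consultations["date"])
    start = extraction_date - pd.Timedelta(days=WINDOW_DAYS)
    return consultations[(dates > start) & (dates <= extraction_date)]


def _register_ids(register: pd.DataFrame | pd.Series | set) -> set:
    """Accept a RegisterResult frame, a membership Series, or a plain set."""
    if isinstance(register, pd.DataFrame):
        if "on_register" in register.columns:
            return set(register.loc[register["on_register"], "patient_id"])
        return set(register["patient_id"])
    if isinstance(register, pd.Series):
        return set(register)
    return set(register)


def consultation_rate(
    register,
    consultations: pd.DataFrame,
    extraction_date: str | pd.Timestamp,
    ltc_name: str = "",
) -> UtilisationSummary:
    """Summarise windowed consultations for members of one register."""
    at = pd.Timestamp(extraction_date)
    members = _register_ids(register)
    if not members:
        logger.warning("empty register %r: rate reported as 0", ltc_name)
        return UtilisationSummary(ltc_name, 0, 0, {c: 0 for c in _CELLS})
    events = _window_events(consultations, at)
    events = events[events["patient_id"].isin(members)]
    counts = events.groupby(["provider", "mode"]).size()
    breakdown = {cell: int(counts.get(cell, 0)) for cell in _CELLS}
    unknown = set(zip(events["provider"], events["mode"])) - set(_CELLS)
    if unknown:
        raise ValueError(f"events with unknown provider/mode cells: {sorted(unknown)}")
    return UtilisationSummary(
        ltc_name=ltc_name,
        n_patients=len(members),
        total_consultations=int(len(events)),
        breakdown=breakdown,
    )


def apply_cost_schedule(
    consultations: pd.DataFrame,
    codebook: Codebook,
    use_recorded_duration: bool = False,
) -> pd.Series:
    """Cost per consultation event, in integer millipence.

    Each event costs its cell's per-minute rate times the cell's mean
    duration; with ``use_recorded_duration`` the event's own recorded duration
    is used instead wherever present. Rounding to whole millipence happens per
    event (banker's rounding via numpy), after which all aggregation is exact
    integer arithmetic; rates quoted to fractions of a penny per minute and
    durations to tenths of a minute are represented without loss.
    """
    if consultations.empty:
        return pd.Series(dtype="int64")
    cells = list(zip(consultations["provider"], consultations["mode"]))
    unknown = set(cells) - set(_CELLS)
    if unknown:
        bad = consultations[
            [c in unknown for c in cells]
        ].iloc[0]
        raise ValueError(
            f"unknown provider/mode for event (patient {bad['patient_id']}, "
            f"{bad['provider']!r}/{bad['mode']!r})"
        )
    rate = np.array(
        [codebook.cost_cell(p, m).rate_per_minute for p, m in cells]
    )
    duration = np.array([codebook.cost_cell(p, m).mean_duration for p, m in cells])
    if use_recorded_duration and "duration" in consultations.columns:
        recorded = pd.to_numeric(consultations["duration"], errors="coerce").to_numpy()
        duration = np.where(np.isfinite(recorded), recorded, duration)
    millipence = np.rint(rate * duration * MILLIPENCE_PER_GBP).astype("int64")
    return pd.Series(millipence, index=consultations.index)


def cost_summary(
    register,
    consultations: pd.DataFrame,
    codebook: Codebook,
    extraction_date: str | pd.Timestamp,
    ltc_name: str = "",
    use_recorded_duration: bool = False,
) -> CostSummary:
    """Total and per-provider annual consultation cost for one register."""
    at = pd.Timestamp(extraction_date)
    members = _register_ids(register)
    events = _window_events(consultations, at)
    events = events[events["patient_id"].isin(members)]
    millipence = apply_cost_schedule(events, codebook, use_recorded_duration)
    by_provider = (
        millipence.groupby(events["provider"]).sum()
        if len(events)
        else pd.Series(dtype="int64")
    )
    provider_cost = {p.value: int(by_provider.get(p.value, 0)) for p in Provider}
    return CostSummary(
        ltc_name=ltc_name,
        n_patients=len(members),
        total_cost_millipence=int(millipence.sum()),
        provider_cost_millipence=provider_cost,
    )


def excess_cost_percent(a: CostSummary, b: CostSummary) -> int:
    """How much higher ``a``'s per-patient cost is than ``b``'s, in percent.

    Computed from the rounded per-patient pound figures (the reported
    quantities) and rounded to an integer percent.
    """
    if b.per_patient_cost_gbp == 0:
        raise ValueError(f"per-patient cost of {b.ltc_name!r} is zero; excess undefined")
    a_pp = a.per_patient_cost_gbp
    b_pp = b.per_patient_cost_gbp
    return int(round((a_pp - b_pp) / b_pp * 100))


_METRICS = {
    "prevalence": lambda row: row["prevalence_percent"],
    "total_consultations": lambda row: row["total_consultations"],
    "total_cost": lambda row: row["total_cost_gbp"],
}


def rank_conditions(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Stable descending sort of a per-condition summary table.

    ``metric`` is one of ``prevalence``, ``total_consultations`` or
    ``total_cost``; ties break alphabetically by ``ltc_name``.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    column = {
        "prevalence": "prevalence_percent",
        "total_consultations": "total_consultations",
        "total_cost": "total_cost_gbp",
    }[metric]
    if column not in table.columns:
        raise ValueError(f"summary table lacks column {column!r}")
    out = table.sort_values(
        [column, "ltc_name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
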