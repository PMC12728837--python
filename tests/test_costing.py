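import numpy as np
import pandas as pd
import pytest

from cpregister.codebook import (
    Codebook,
    CostScheduleEntry,
    Mode,
    Provider,
    default_codebook,
)
from cpregister.cohort import build_cohort
from cpregister.costing import (
    MILLIPENCE_PER_GBP,
    CostSummary,
    UtilisationSummary,
    apply_cost_schedule,
    consultation_rate,
    cost_summary,
    excess_cost_percent,
    rank_conditions,
)

from .conftest import EXTRACTION, make_events

CONS_COLS = ["patient_id", "date", "provider", "mode", "duration"]


def schedule_with(gp_f2f: float, nurse_tel: float) -> Codebook:
    """Default codebook with two cells pinned to exact per-event costs."""
    cb = default_codebook()
    cells = []
    for e in cb.cost_schedule:
        if (e.provider, e.mode) == (Provider.gp, Mode.face_to_face):
            cells.append(CostScheduleEntry(provider=e.provider, mode=e.mode,
                                           rate_per_minute=gp_f2f / 10.0, mean_duration=10.0))
        elif (e.provider, e.mode) == (Provider.nurse, Mode.telephone):
            cells.append(CostScheduleEntry(provider=e.provider, mode=e.mode,
                                           rate_per_minute=nurse_tel / 10.0, mean_duration=10.0))
        else:
            cells.append(e)
    return Codebook(medications=cb.medications, conditions=cb.conditions,
                    ltcs=cb.ltcs, cost_schedule=tuple(cells))


class TestConsultationRate:
    @pytest.mark.parametrize(
        "total,n,expected",
        [(932_023, 61_042, 15.3), (814_188, 70_181, 11.6), (0, 10, 0.0)],
    )
    def test_mean_rate_rounding(self, total, n, expected):
        summary = UtilisationSummary("x", n, total, {})
        assert summary.mean_rate == expected

    def test_counts_window_events_of_members_only(self):
        cons = make_events(
            [
                ("A", "2023-05-01", "gp", "face_to_face", 10.0),
                ("A", "2022-05-01", "gp", "face_to_face", 10.0),  # outside window
                ("B", "2023-05-01", "gp", "telephone", 5.0),  # not a member
            ],
            CONS_COLS,
        )
        summary = consultation_rate({"A"}, cons, EXTRACTION, "cp")
        assert summary.total_consultations == 1
        assert summary.breakdown[("gp", "face_to_face")] == 1

    def test_empty_register_reports_zero(self):
        summary = consultation_rate(set(), make_events([], CONS_COLS), EXTRACTION)
        assert summary.n_patients == 0 and summary.mean_rate == 0.0

    def test_breakdown_sums_to_total(self, codebook, small_bundle):
        cohort, _ = build_cohort(small_bundle.patients, EXTRACTION)
        summary = consultation_rate(
            set(cohort["patient_id"]), small_bundle.consultations, EXTRACTION, "all"
        )
        assert sum(summary.breakdown.values()) == summary.total_consultations


class TestCostSchedule:
    def test_hand_summed_fixture(self):
        """Three GP face-to-face at GBP 42 plus one nurse call at GBP 10 = GBP 136."""
        cb = schedule_with(gp_f2f=42.0, nurse_tel=10.0)
        cons = make_events(
            [("A", "2023-05-01", "gp", "face_to_face", None)] * 3
            + [("A", "2023-05-02", "nurse", "telephone", None)],
            CONS_COLS,
        )
        assert apply_cost_schedule(cons, cb).sum() == 136 * MILLIPENCE_PER_GBP

    def test_empty_events_cost_nothing(self, codebook):
        assert apply_cost_schedule(make_events([], CONS_COLS), codebook).sum() == 0

    def test_unknown_cell_errors_naming_event(self, codebook):
        cons = make_events([("A", "2023-05-01", "gp", "carrier_pigeon", None)], CONS_COLS)
        with pytest.raises(ValueError, match="carrier_pigeon"):
            apply_cost_schedule(cons, codebook)

    def test_recorded_duration_used_when_flagged(self):
        cb = schedule_with(gp_f2f=40.0, nurse_tel=10.0)  # GBP 4/min for GP f2f
        cons = make_events([("A", "2023-05-01", "gp", "face_to_face", 5.0)], CONS_COLS)
        assert apply_cost_schedule(cons, cb).sum() == 40 * MILLIPENCE_PER_GBP
        assert (
            apply_cost_schedule(cons, cb, use_recorded_duration=True).sum()
            == 20 * MILLIPENCE_PER_GBP
        )

    def test_doubling_rates_doubles_costs(self, codebook, small_bundle):
        doubled = Codebook(
            medications=codebook.medications,
            conditions=codebook.conditions,
            ltcs=codebook.ltcs,
            cost_schedule=tuple(
                CostScheduleEntry(
                    provider=e.provider, mode=e.mode,
                    rate_per_minute=2 * e.rate_per_minute, mean_duration=e.mean_duration,
                )
                for e in codebook.cost_schedule
            ),
        )
        base = apply_cost_schedule(small_bundle.consultations, codebook)
        twice = apply_cost_schedule(small_bundle.consultations, doubled)
        assert (twice == 2 * base).all()


class TestCostSummary:
    def test_components_sum_exactly_to_total(self, codebook, small_bundle):
        cohort, _ = build_cohort(small_bundle.patients, EXTRACTION)
        summary = cost_summary(
            set(cohort["patient_id"]), small_bundle.consultations, codebook, EXTRACTION, "all"
        )
        assert sum(summary.provider_cost_millipence.values()) == summary.total_cost_millipence

    def test_component_fixture(self):
        cb = schedule_with(gp_f2f=100.0, nurse_tel=50.0)
        cons = make_events(
            [
                ("A", "2023-05-01", "gp", "face_to_face", None),
                ("A", "2023-05-02", "nurse", "telephone", None),
            ],
            CONS_COLS,
        )
        summary = cost_summary({"A"}, cons, cb, EXTRACTION, "fix")
        assert summary.total_cost_millipence == 150 * MILLIPENCE_PER_GBP
        assert summary.provider_cost_millipence["gp"] == 100 * MILLIPENCE_PER_GBP
        assert summary.provider_cost_millipence["nurse"] == 50 * MILLIPENCE_PER_GBP
        assert summary.provider_cost_millipence["other_hcp"] == 0


class TestExcessCost:
    def test_headline_comparison(self):
        """GBP 373 vs GBP 289 per patient is a 29% excess."""
        a = CostSummary("cp", 61_042, 373 * MILLIPENCE_PER_GBP * 61_042, {})
        b = CostSummary("anxiety", 70_181, 289 * MILLIPENCE_PER_GBP * 70_181, {})
        assert a.per_patient_cost_gbp == 373
        assert b.per_patient_cost_gbp == 289
        assert excess_cost_percent(a, b) == 29

    def test_equal_summaries_zero_excess(self):
        a = CostSummary("a", 10, 500 * MILLIPENCE_PER_GBP, {})
        assert excess_cost_percent(a, a) == 0

    def test_zero_baseline_errors(self):
        a = CostSummary("a", 10, 500 * MILLIPENCE_PER_GBP, {})
        z = CostSummary("z", 10, 0, {})
        with pytest.raises(ValueError, match="zero"):
            excess_cost_percent(a, z)


class TestRanking:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "ltc_name": ["anxiety", "chronic_pain", "asthma"],
                "prevalence_percent": [21.4, 18.6, 11.7],
                "total_consultations": [814_188, 932_023, 300_000],
                "total_cost_gbp": [20.2e6, 22.7e6, 9.7e6],
            }
        )

    def test_prevalence_puts_anxiety_first(self, table):
        ranked = rank_conditions(table, "prevalence")
        assert list(ranked["ltc_name"][:2]) == ["anxiety", "chronic_pain"]

    def test_cost_puts_chronic_pain_first(self, table):
        ranked = rank_conditions(table, "total_cost")
        assert ranked["ltc_name"].iloc[0] == "chronic_pain"

    def test_ties_break_alphabetically(self, table):
        table.loc[:, "total_cost_gbp"] = 1.0
        ranked = rank_conditions(table, "total_cost")
        assert list(ranked["ltc_name"]) == sorted(table["ltc_name"])

    def test_unknown_metric_errors(self, table):
        with pytest.raises(ValueError, match="unknown metric"):
            rank_conditions(table, "sparkle")

    def test_single_row(self, table):
        ranked = rank_conditions(table.iloc[:1], "prevalence")
        assert len(ranked) == 1 and ranked["rank"].iloc[0] == 1
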