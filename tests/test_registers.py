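import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pandas.testing import assert_frame_equal

from cpregister.cohort import build_cohort
from cpregister.registers import (
    build_cp_register,
    build_ltc_register,
    count_analgesic_prescriptions,
    diagnostic_criterion,
    medication_criterion,
)
from cpregister.synthetic import inner_london_config, simulate_population

from .conftest import EXTRACTION, make_events, make_patients
from .oracles import brute_force_register

RX_COLS = ["patient_id", "date", "medication_code"]
DX_COLS = ["patient_id", "date", "condition_code"]
EMPTY_RX = make_events([], RX_COLS)
EMPTY_DX = make_events([], DX_COLS)


class TestAnalgesicCounting:
    def test_four_opioid_issues_count_four(self, codebook):
        rx = make_events(
            [("P0", f"2023-0{m}-10", "MED-OPI-01") for m in range(3, 7)], RX_COLS
        )
        assert count_analgesic_prescriptions(rx, EMPTY_DX, "P0", EXTRACTION, codebook) == 4

    def test_antiepileptics_nullified_by_epilepsy_code(self, codebook):
        rx = make_events(
            [("P0", f"2023-0{m}-10", "MED-AED-01") for m in range(3, 7)], RX_COLS
        )
        epilepsy_code = next(
            c.condition_code
            for c in codebook.conditions
            if c.dual_indication_for is not None and c.dual_indication_for.value == "antiepileptic"
        )
        dx = make_events([("P0", "2010-05-01", epilepsy_code)], DX_COLS)
        assert count_analgesic_prescriptions(rx, dx, "P0", EXTRACTION, codebook) == 0
        # without the epilepsy code the same issues count in full
        assert count_analgesic_prescriptions(rx, EMPTY_DX, "P0", EXTRACTION, codebook) == 4

    def test_issues_outside_window_not_counted(self, codebook):
        rx = make_events(
            [("P0", "2022-07-10", "MED-OPI-01") for _ in range(4)], RX_COLS
        )  # 13+ months before extraction
        assert count_analgesic_prescriptions(rx, EMPTY_DX, "P0", EXTRACTION, codebook) == 0

    def test_same_day_same_code_collapses_to_one_issue(self, codebook):
        rx = make_events(
            [("P0", "2023-05-10", "MED-OPI-01")] * 3
            + [("P0", "2023-05-10", "MED-OPI-02")],
            RX_COLS,
        )
        assert count_analgesic_prescriptions(rx, EMPTY_DX, "P0", EXTRACTION, codebook) == 2

    def test_otc_and_non_analgesics_not_counted(self, codebook):
        rx = make_events(
            [
                ("P0", "2023-05-01", "MED-SIM-90"),  # not prescription-only
                ("P0", "2023-05-02", "MED-NON-01"),  # not an analgesic
                ("P0", "2023-05-03", "MED-UNKNOWN"),  # not in the codebook
            ],
            RX_COLS,
        )
        assert count_analgesic_prescriptions(rx, EMPTY_DX, "P0", EXTRACTION, codebook) == 0


class TestMedicationCriterion:
    @pytest.mark.parametrize("count,expected", [(0, False), (3, False), (4, True), (9, True)])
    def test_threshold(self, count, expected):
        assert medication_criterion(count) is expected


class TestDiagnosticCriterion:
    def test_tier1_fires_without_analgesics(self, codebook):
        dx = make_events([("P0", "2018-01-01", "CND-T1-03")], DX_COLS)
        assert diagnostic_criterion(dx, 0, "P0", codebook, EXTRACTION) == (True, 1)

    @pytest.mark.parametrize("count,expected", [(2, (False, None)), (3, (True, 2))])
    def test_tier2_needs_three_analgesics(self, codebook, count, expected):
        dx = make_events([("P0", "2018-01-01", "CND-T2-07")], DX_COLS)
        assert diagnostic_criterion(dx, count, "P0", codebook, EXTRACTION) == expected

    def test_cancer_pain_never_fires(self, codebook):
        dx = make_events([("P0", "2018-01-01", "CND-CA-01")], DX_COLS)
        assert diagnostic_criterion(dx, 9, "P0", codebook, EXTRACTION) == (False, None)

    def test_diagnosis_lookback_is_lifetime(self, codebook):
        dx = make_events([("P0", "1999-01-01", "CND-T1-01")], DX_COLS)
        assert diagnostic_criterion(dx, 0, "P0", codebook, EXTRACTION) == (True, 1)


class TestCpRegister:
    def test_both_criteria_flagged(self, codebook):
        cohort = make_patients([{}])
        rx = make_events(
            [("P000", f"2023-0{m}-01", "MED-NSA-01") for m in range(2, 7)], RX_COLS
        )
        dx = make_events([("P000", "2020-01-01", "CND-T1-02")], DX_COLS)
        reg = build_cp_register(cohort, rx, dx, codebook, EXTRACTION)
        row = reg.iloc[0]
        assert row["on_register"]
        assert row["medication_criterion"] and row["diagnostic_criterion"]
        assert row["triggering_tier"] == 1

    def test_empty_event_tables_give_empty_register(self, codebook):
        cohort = make_patients([{}, {}, {}])
        reg = build_cp_register(cohort, EMPTY_RX, EMPTY_DX, codebook, EXTRACTION)
        assert not reg["on_register"].any()
        assert (reg["analgesic_count"] == 0).all()

    def test_events_for_non_cohort_patients_ignored(self, codebook):
        cohort = make_patients([{}])
        rx = make_events(
            [("GHOST", f"2023-0{m}-01", "MED-OPI-01") for m in range(2, 7)], RX_COLS
        )
        reg = build_cp_register(cohort, rx, EMPTY_DX, codebook, EXTRACTION)
        assert not reg["on_register"].any()

    def test_result_invariants_on_synthetic_bundle(self, codebook, small_bundle):
        cohort, _ = build_cohort(small_bundle.patients, EXTRACTION)
        reg = build_cp_register(
            cohort, small_bundle.prescriptions, small_bundle.diagnoses, codebook, EXTRACTION
        )
        assert (reg["on_register"] == (reg["medication_criterion"] | reg["diagnostic_criterion"])).all()
        assert (reg.loc[reg["medication_criterion"], "analgesic_count"] >= 4).all()
        tier2 = reg["triggering_tier"] == 2
        assert (reg.loc[tier2, "analgesic_count"] >= 3).all()

    def test_matches_bruteforce_on_bundle(self, codebook):
        bundle = simulate_population(inner_london_config(n_patients=500, seed=42), codebook)
        cohort, _ = build_cohort(bundle.patients, EXTRACTION)
        fast = build_cp_register(
            cohort, bundle.prescriptions, bundle.diagnoses, codebook, EXTRACTION
        )
        slow = brute_force_register(
            cohort, bundle.prescriptions, bundle.diagnoses, codebook, EXTRACTION
        )
        assert_frame_equal(fast, slow, check_dtype=False)


class TestMonotonicity:
    @settings(max_examples=25, deadline=None)
    @given(
        n_rx=st.integers(min_value=0, max_value=8),
        with_tier2=st.booleans(),
        extra_day=st.integers(min_value=0, max_value=364),
    )
    def test_adding_an_analgesic_never_removes_from_register(
        self, n_rx, with_tier2, extra_day
    ):
        from cpregister.codebook import default_codebook

        codebook = default_codebook()
        cohort = make_patients([{}])
        rx_rows = [
            ("P000", EXTRACTION - pd.Timedelta(days=30 * i + 1), "MED-OPI-01")
            for i in range(n_rx)
        ]
        dx = (
            make_events([("P000", "2019-06-01", "CND-T2-01")], DX_COLS)
            if with_tier2
            else EMPTY_DX
        )
        before = build_cp_register(
            cohort, make_events(rx_rows, RX_COLS), dx, codebook, EXTRACTION
        )
        extra = ("P000", EXTRACTION - pd.Timedelta(days=extra_day), "MED-NSA-02")
        after = build_cp_register(
            cohort, make_events(rx_rows + [extra], RX_COLS), dx, codebook, EXTRACTION
        )
        assert after["analgesic_count"].iloc[0] >= before["analgesic_count"].iloc[0]
        if before["on_register"].iloc[0]:
            assert after["on_register"].iloc[0]


class TestLtcRegister:
    def test_single_code_puts_patient_on_register(self, codebook):
        cohort = make_patients([{}, {}])
        anxiety_code = sorted(codebook.ltc("anxiety").condition_codes)[0]
        dx = make_events([("P000", "2021-03-04", anxiety_code)], DX_COLS)
        reg = build_ltc_register(cohort, dx, codebook, "anxiety", EXTRACTION)
        assert reg.set_index("patient_id")["on_register"].to_dict() == {
            "P000": True, "P001": False,
        }

    def test_code_after_extraction_not_counted(self, codebook):
        cohort = make_patients([{}])
        anxiety_code = sorted(codebook.ltc("anxiety").condition_codes)[0]
        dx = make_events([("P000", "2023-09-01", anxiety_code)], DX_COLS)
        reg = build_ltc_register(cohort, dx, codebook, "anxiety", EXTRACTION)
        assert not reg["on_register"].any()

    def test_unknown_ltc_name_errors(self, codebook):
        cohort = make_patients([{}])
        with pytest.raises(KeyError):
            build_ltc_register(cohort, EMPTY_DX, codebook, "gondor_fever", EXTRACTION)
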