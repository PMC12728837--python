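import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from cpregister.synthetic import (
    BundleIntegrityError,
    SimulationConfig,
    calibrate_base_consultation_mean,
    calibrate_intercept,
    inner_london_config,
    read_bundle,
    simulate_population,
    write_bundle,
)

from .conftest import EXTRACTION


class TestConfigValidation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(sex_probs={"male": 0.6, "female": 0.5})

    def test_zero_patients_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_patients=0)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(consult_dispersion=0.0)

    def test_comparator_mean_may_not_exceed_cp_mean(self):
        with pytest.raises(ValueError, match="must not exceed"):
            SimulationConfig(ltc_consult_mean={"anxiety": 30.0, "depression": 9.0,
                                               "hypertension": 9.5, "asthma": 7.0})


class TestCalibration:
    def test_intercept_hits_target_prevalence_in_expectation(self):
        """Exact-enumeration check: calibrated intercept, plugged back into the
        enumerated covariate distribution, yields the target prevalence."""
        from cpregister.synthetic import _logit_eta_components
        from scipy.special import expit

        cfg = inner_london_config()
        b0 = calibrate_intercept(cfg)
        probs = np.array([1.0])
        etas = np.array([0.0])
        for _, p, lor in _logit_eta_components(cfg):
            probs = np.multiply.outer(probs, np.asarray(p)).ravel()
            etas = np.add.outer(etas, np.asarray(lor)).ravel()
        assert np.dot(probs, expit(b0 + etas)) == pytest.approx(0.186, abs=1e-9)

    def test_explicit_intercept_respected(self):
        cfg = inner_london_config(intercept=-2.0)
        assert calibrate_intercept(cfg) == -2.0

    def test_base_mean_solves_overall_target(self):
        """Monte-Carlo cross-check of the closed-form base-mean solution."""
        cfg = inner_london_config()
        base = calibrate_base_consultation_mean(cfg)
        rng = np.random.default_rng(0)
        n = 400_000
        mu = np.full(n, base)
        for name, q in cfg.ltc_prevalence.items():
            member = rng.random(n) < q
            mu = np.where(member, np.maximum(mu, cfg.ltc_consult_mean[name]), mu)
        cp = rng.random(n) < cfg.target_prevalence
        mu = np.where(cp, cfg.cp_consult_mean, mu)
        assert mu.mean() == pytest.approx(cfg.overall_consult_mean, abs=0.02)

    def test_unreachable_overall_mean_rejected(self):
        cfg = inner_london_config(overall_consult_mean=2.0)
        with pytest.raises(ValueError, match="too low"):
            calibrate_base_consultation_mean(cfg)


class TestDeterminism:
    def test_same_seed_same_bundle(self, codebook):
        cfg = inner_london_config(n_patients=800, seed=9)
        a = simulate_population(cfg, codebook)
        b = simulate_population(cfg, codebook)
        assert a == b

    def test_different_seeds_differ(self, codebook):
        a = simulate_population(inner_london_config(n_patients=800, seed=1), codebook)
        b = simulate_population(inner_london_config(n_patients=800, seed=2), codebook)
        assert not a.truth["cp"].equals(b.truth["cp"])


@pytest.fixture(scope="module")
def big_bundle(codebook):
    return simulate_population(inner_london_config(n_patients=100_000, seed=21), codebook)


class TestMarginals:
    def test_white_fraction_of_known_ethnicity(self, big_bundle):
        known = big_bundle.patients[big_bundle.patients["ethnicity"] != "unknown"]
        white = (known["ethnicity"] == "White").mean()
        assert white == pytest.approx(0.585, abs=0.005)

    def test_every_age_band_populated(self, codebook):
        bundle = simulate_population(inner_london_config(n_patients=10_000, seed=3), codebook)
        from cpregister.cohort import build_cohort

        cohort, _ = build_cohort(bundle.patients, EXTRACTION)
        assert cohort["age_band"].value_counts().min() > 0

    def test_missingness_rates(self, big_bundle):
        lang_missing = big_bundle.patients["language_preference"].isna().mean()
        ctry_missing = big_bundle.patients["country_of_birth"].isna().mean()
        assert lang_missing == pytest.approx(0.241, abs=0.01)
        assert ctry_missing == pytest.approx(0.458, abs=0.01)


class TestBundleIO:
    def test_round_trip_identity(self, codebook, tmp_path):
        bundle = simulate_population(inner_london_config(n_patients=100, seed=5), codebook)
        write_bundle(bundle, tmp_path / "b")
        loaded = read_bundle(tmp_path / "b")
        assert loaded == bundle

    def test_orphan_event_rejected_on_read(self, codebook, tmp_path):
        bundle = simulate_population(inner_london_config(n_patients=50, seed=5), codebook)
        write_bundle(bundle, tmp_path / "b")
        rx_path = tmp_path / "b" / "prescriptions.csv"
        with open(rx_path, "a") as fh:
            fh.write("GHOST,2023-01-01,MED-OPI-01\n")
        with pytest.raises(BundleIntegrityError, match="GHOST"):
            read_bundle(tmp_path / "b")

    def test_missing_file_named_in_error(self, codebook, tmp_path):
        bundle = simulate_population(inner_london_config(n_patients=50, seed=5), codebook)
        write_bundle(bundle, tmp_path / "b")
        (tmp_path / "b" / "diagnoses.csv").unlink()
        with pytest.raises(FileNotFoundError, match="diagnoses.csv"):
            read_bundle(tmp_path / "b")

    def test_empty_consultations_read_fine(self, codebook, tmp_path):
        bundle = simulate_population(inner_london_config(n_patients=50, seed=5), codebook)
        write_bundle(bundle, tmp_path / "b")
        path = tmp_path / "b" / "consultations.csv"
        path.write_text("patient_id,date,provider,mode,duration\n")
        loaded = read_bundle(tmp_path / "b")
        assert loaded.consultations.empty

    def test_events_never_postdate_extraction(self, small_bundle):
        for table in (small_bundle.prescriptions, small_bundle.diagnoses,
                      small_bundle.consultations):
            assert (pd.to_datetime(table["date"]) <= EXTRACTION).all()
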