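import pandas as pd
import pytest

from cpregister.codebook import default_codebook
from cpregister.synthetic import inner_london_config, simulate_population

EXTRACTION = pd.Timestamp("2023-08-31")


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def small_bundle(codebook):
    """A 2000-patient default-preset bundle shared across tests."""
    return simulate_population(inner_london_config(n_patients=2000, seed=11), codebook)


def make_patients(rows: list[dict]) -> pd.DataFrame:
    """Hand-built patient table with sensible defaults per row."""
    defaults = dict(
        birth_date="1970-01-01",
        sex="female",
        ethnicity="White",
        imd_score=50.0,
        language_preference="English",
        country_of_birth="UK",
        registration_start="2015-01-01",
        registration_end="2023-08-31",
        dissent=False,
    )
    out = []
    for i, row in enumerate(rows):
        rec = {"patient_id": f"P{i:03d}", **defaults, **row}
        out.append(rec)
    df = pd.DataFrame(out)
    for col in ("birth_date", "registration_start", "registration_end"):
        df[col] = pd.to_datetime(df[col])
    return df


def make_events(rows: list[tuple], columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=columns)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df
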