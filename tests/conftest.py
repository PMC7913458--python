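import numpy as np
import pandas as pd
import pytest

from rarestay.catalogue import Catalogue, CatalogueEntry


@pytest.fixture(scope="session")
def sickle_catalogue() -> Catalogue:
    """Small hand-built catalogue exercising 3- and 4-character codes."""
    return Catalogue(
        [
            CatalogueEntry("D57", "Sickle-cell disorders"),
            CatalogueEntry("Q05", "Spina bifida"),
            CatalogueEntry("A924", "Rift Valley fever"),
            CatalogueEntry("E750", "GM2 gangliosidosis"),
        ]
    )


def make_stays(rows: list[dict]) -> pd.DataFrame:
    """Stay table from partial dicts, with sensible defaults filled in."""
    defaults = {
        "age_at_admission": 50,
        "sex": "F",
        "admit_date": "2012-01-10",
        "discharge_date": "2012-01-15",
        "died_in_hospital": 0,
        "icu_admitted": 0,
        "icu_days": 0.0,
        "los_days": 5.0,
        "discharge_year": 2012,
        "unit_group": "internal-medicine-and-related",
        "readmission_info_complete": 1,
        "previous_stays_2y": 0,
        "readmitted_30d": 0,
    }
    full = []
    for i, row in enumerate(rows):
        rec = {"stay_id": i, "patient_id": i, **defaults, **row}
        full.append(rec)
    return pd.DataFrame(full)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared small synthetic population for structural tests."""
    from rarestay.simulate import SyntheticConfig, generate_population

    return generate_population(SyntheticConfig(n_patients=4000, seed=20250930))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
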