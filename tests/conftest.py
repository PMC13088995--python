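import pandas as pd
import pytest

from aviahealth import (
    WorldConfig,
    default_scenarios,
    generate_world,
    load_erf_table,
)


@pytest.fixture(scope="session")
def tiny_world():
    """Seeded 3-airport world over 2025-2027 (plus 2050 for ramp endpoints)."""
    return generate_world(3, seed=7, years=range(2025, 2028))


@pytest.fixture(scope="session")
def small_world():
    """Seeded 3-airport world over the full assessment window."""
    return generate_world(3, seed=11, years=range(2025, 2051))


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def erf_table():
    return load_erf_table()


@pytest.fixture()
def world_config():
    return WorldConfig()


@pytest.fixture(scope="session")
def uniform_stratum_tables():
    """One airport, all strata, flat rate 0.01 — for hand-checkable accounting."""
    from aviahealth.constants import AGE_BANDS, DISEASES, SEXES

    pop = pd.DataFrame(
        [("AP0000", band, sex, 100_000.0) for band in AGE_BANDS for sex in SEXES],
        columns=["airport_id", "age_band", "sex", "count"])
    rates = pd.DataFrame(
        [(d, band, sex, 0.01) for d in DISEASES for band in AGE_BANDS for sex in SEXES],
        columns=["disease_id", "age_band", "sex", "rate"])
    return pop, rates
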