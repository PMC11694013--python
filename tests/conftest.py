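import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tenamericas.config import SyntheticConfig
from tenamericas.synthetic import generate_vitals

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# A schedule with plausible adult mortality used by several life-table tests
# (19 groups: 0, 1-4, 5-9, ..., 80-84, 85+).
HAND_M_SCHEDULE = np.array(
    [0.006, 0.0003, 0.0002, 0.0003, 0.0006, 0.0008, 0.0009, 0.0011, 0.0015,
     0.0022, 0.0033, 0.0050, 0.0078, 0.0120, 0.0190, 0.0300, 0.0480, 0.0780,
     0.1550]
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_counties=60, years=(2018, 2021), seed=3)


@pytest.fixture(scope="session")
def vitals(small_config):
    return generate_vitals(small_config)


@pytest.fixture
def hand_m_schedule() -> np.ndarray:
    return HAND_M_SCHEDULE.copy()


@pytest.fixture
def tiny_attrs() -> pd.DataFrame:
    """Six hand-built counties spanning several classification rules."""
    rows = [
        # county, state, rucc, D-index, nhpi, app, lmv, deep_south, incomes...
        ("C0", "TX", 1, 72.0, 0.10, False, False, False, 40_000, 40_000, 40_000, 40_000, 40_000),
        ("C1", "MS", 6, 30.0, 0.05, False, True, True, 25_000, 25_000, 25_000, 25_000, 28_000),
        ("C2", "ND", 8, 10.0, 0.02, False, False, False, 30_000, 35_000, 33_000, 31_000, 30_000),
        ("C3", "WV", 7, 20.0, 0.01, True, False, False, 28_000, 30_000, 29_000, 27_000, 28_000),
        ("C4", "CA", 1, 45.0, 0.40, False, False, False, 60_000, 70_000, 50_000, 45_000, 65_000),
        ("C5", "AZ", 4, 55.0, 0.20, False, False, False, 26_000, 40_000, 33_000, 30_000, 36_000),
    ]
    cols = ["county_id", "state", "rucc", "dissimilarity_index", "nhpi_share",
            "appalachia", "lower_mississippi_valley", "deep_south",
            "income_AIAN", "income_Asian", "income_Black", "income_Latino",
            "income_White"]
    return pd.DataFrame(rows, columns=cols)
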