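import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sice import MISSING, DataTable, VariableSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TABLE1_SCHEMA = [
    VariableSpec("Serial", "numeric"),
    VariableSpec("Gender", "binary", ("Female", "Male")),
    VariableSpec("Income", "numeric"),
]

# Toy income table: two missing Income cells; observed mean is 180.
TABLE1_ROWS = [
    [1, "Female", 100],
    [2, "Female", MISSING],
    [3, "Male", 100],
    [4, "Female", 300],
    [5, "Male", MISSING],
    [6, "Male", 200],
    [7, "Female", 200],
]

DEATH_LEVELS = ("Covid-19", "Heart attack", "Cancer")

TABLE3_SCHEMA = [
    VariableSpec("Serial", "numeric"),
    VariableSpec("Age", "numeric"),
    VariableSpec("DeathReason", "nominal", DEATH_LEVELS),
]

# Toy mortality table: three missing causes; the observed mode is "Cancer".
TABLE3_ROWS = [
    [1, 60, "Covid-19"],
    [2, 64, MISSING],
    [3, 42, "Heart attack"],
    [4, 67, "Covid-19"],
    [5, 80, MISSING],
    [6, 32, "Cancer"],
    [7, 35, "Cancer"],
    [8, 45, "Cancer"],
    [9, 88, MISSING],
    [10, 33, "Heart attack"],
]


@pytest.fixture
def income_table() -> DataTable:
    return DataTable(TABLE1_SCHEMA, TABLE1_ROWS)


@pytest.fixture
def death_table() -> DataTable:
    return DataTable(TABLE3_SCHEMA, TABLE3_ROWS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
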