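import pytest
from hypothesis import HealthCheck, settings

from agreemip import PenaltyTable, load_penalty_table

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_table() -> PenaltyTable:
    return load_penalty_table()


@pytest.fixture(scope="session")
def tiny_table() -> PenaltyTable:
    return PenaltyTable(
        {"H225": 6, "H301": 8, "H360": 10, "H400": 6}, source_label="test-table"
    )
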