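import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import illusim as il

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1_config() -> il.ExperimentConfig:
    return il.load_preset("exp1")


@pytest.fixture(scope="session")
def exp1_table(exp1_config) -> il.PSETable:
    """One simulated experiment-shaped PSE table (20 x 2 x 5), fixed seed."""
    table, _ = il.simulate_replicate(exp1_config, 123)
    return table


@pytest.fixture(scope="session")
def toy_table() -> il.PSETable:
    """4 subjects x 2 shadow levels at a single orientation."""
    rng = np.random.default_rng(42)
    wide = rng.normal(100.0, 2.0, size=(4, 2, 1))
    wide[:, 1, 0] += 3.0
    return il.PSETable.from_wide(wide, angles=[0.0])


@pytest.fixture()
def threshold_observer() -> il.ThresholdObserver:
    return il.ThresholdObserver(subject_id="t01", threshold=100.0)
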