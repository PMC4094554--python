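import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140711)


@pytest.fixture
def small_matrix(rng):
    """10-gene x 50-sample matrix with 2 noiseless linear targets."""
    reg = rng.standard_normal(50)
    rows = {"REG": reg, "T1": -2.0 * reg, "T2": 1.5 * reg}
    for i in range(7):
        rows[f"BG{i}"] = rng.standard_normal(50)
    m = pd.DataFrame(rows).T
    m.columns = [f"S{j}" for j in range(50)]
    m.index.name = "gene"
    return m
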