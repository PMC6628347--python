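import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from evmir import CtMatrix, load_table2_fixture

settings.register_profile(
    "evmir",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("evmir")


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture
def small_ct():
    """3 probes x 4 samples; probe B undetected everywhere."""
    values = pd.DataFrame(
        {
            "s1": [25.0, 40.0, 30.0],
            "s2": [26.0, 40.0, 31.0],
            "s3": [24.0, 40.0, 29.0],
            "s4": [25.5, 40.0, 30.5],
        },
        index=["A", "B", "C"],
    )
    return CtMatrix(values)


@pytest.fixture
def two_group_meta():
    return pd.Series(
        ["case", "case", "control", "control"],
        index=["s1", "s2", "s3", "s4"],
        name="group",
    )


def random_ct_frame(rng: np.random.Generator, n_probes: int, n_samples: int,
                    p_undetected: float = 0.3, ct_max: float = 40.0) -> pd.DataFrame:
    values = rng.uniform(10, 39, size=(n_probes, n_samples))
    values[rng.random((n_probes, n_samples)) < p_undetected] = ct_max
    return pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
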