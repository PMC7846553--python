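import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from paritynet.dataset import CONTRAST_GROUP, REFERENCE_GROUP, ExpressionDataset
from paritynet.simulate import generate_dataset, null_config, study_config

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_dataset(values: np.ndarray, n1: int, n2: int) -> ExpressionDataset:
    """Wrap a raw matrix whose first n1 columns are the reference group."""
    p, n = values.shape
    assert n == n1 + n2
    samples = [f"s{i}" for i in range(n)]
    groups = pd.Series([REFERENCE_GROUP] * n1 + [CONTRAST_GROUP] * n2, index=samples)
    frame = pd.DataFrame(values, index=[f"P{i:04d}" for i in range(p)], columns=samples)
    return ExpressionDataset(frame, groups)


@pytest.fixture(scope="session")
def study_data():
    """600-probe dataset with every planted block, n = 42/71."""
    ds, truth = generate_dataset(study_config(600, seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def null_data():
    """400-probe dataset with no planted effects."""
    ds, _ = generate_dataset(null_config(400, seed=13))
    return ds
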