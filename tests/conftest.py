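import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import inktqsar as iq

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

REFERENCE = "CPD-001"


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic dataset: 60 compounds, all five
    test-models, sparse measurement, 50% study noise."""
    config = iq.GeneratorConfig(seed=11)
    descriptors, records, truth = iq.generate_dataset(config)
    return config, descriptors, records, truth


@pytest.fixture(scope="session")
def normalized_small(small_dataset):
    _, _, records, _ = small_dataset
    parsed = iq.read_response_table(records)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return iq.normalize_to_reference(parsed, REFERENCE)


@pytest.fixture(scope="session")
def matrix_small(normalized_small):
    return iq.aggregate_replicates(normalized_small, REFERENCE)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_matrix(values: dict, reference=REFERENCE) -> iq.RelativeResponseMatrix:
    """Hand-built RelativeResponseMatrix from {(system, marker): {cid: y}}."""
    frame = pd.DataFrame(values)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["test_system", "marker"])
    counts = frame.notna().astype(int)
    return iq.RelativeResponseMatrix(values=frame, n_sources=counts,
                                     reference_id=reference)
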