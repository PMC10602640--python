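import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from micromarker import CohortConfig, generate_cohort, preprocess
from micromarker.containers import response_vector

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One 105-sample cohort at the package's default study conditions."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def processed_cohort(default_cohort):
    """Default cohort taken through the standard preprocessing chain."""
    matrix, meta, truth = default_cohort
    matrix = preprocess.retain_bacteria(matrix)
    matrix, _ = preprocess.prevalence_contaminant_filter(matrix)
    matrix = preprocess.rarefy(matrix, seed=7)
    rel = preprocess.to_relative(matrix)
    labels = response_vector(meta, matrix.sample_ids)
    return matrix, rel, labels, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
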