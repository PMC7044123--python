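from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import lipidzc as L
from lipidzc.synth import quantify_synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-condition synthetic gradient survey (fixed seed)."""
    return L.generate_dataset(L.GradientConfig(seed=7))


@pytest.fixture(scope="session")
def quantified(synthetic_dataset):
    return quantify_synthetic(synthetic_dataset)


@pytest.fixture(scope="session")
def summaries(quantified):
    return L.summarize_dataset(quantified)


def records_with_x(pairs, sample_id="T"):
    """Build quantified records directly from (annotation, mole fraction)."""
    recs = L.build_records([(sample_id, name, 1.0) for name, _ in pairs])
    return [replace(r, x=x) for r, (_, x) in zip(recs, pairs)]


@pytest.fixture
def make_records():
    return records_with_x
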