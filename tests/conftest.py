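import pytest
from hypothesis import HealthCheck, settings

import cnanet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """One small synthetic fixture shared by integration-level tests."""
    d = tmp_path_factory.mktemp("fixture")
    truth = cnanet.make_end_to_end_fixture(d, profile="small", seed=42)
    return d, truth


@pytest.fixture(scope="session")
def pipeline_result(small_fixture):
    d, truth = small_fixture
    return cnanet.run_pipeline(d), truth
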