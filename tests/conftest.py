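import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pneumorisk import (  # noqa: E402
    ReclassificationAnalysis,
    fixture_cohort,
    published_clinical_model,
    published_crp_model,
)


@pytest.fixture(scope="session")
def fixture():
    """The deterministic 249-record reconstruction cohort."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def reclass_results(fixture):
    """Reclassification of the fixture under the two published equations."""
    return ReclassificationAnalysis(
        fixture, published_clinical_model(), published_crp_model()
    ).fit()
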