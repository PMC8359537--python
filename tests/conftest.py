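import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmetspipe.synthetic import generate_cohort, paper_like_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-like synthetic cohort (n=386, fixed seed), session-shared."""
    return generate_cohort(paper_like_config(seed=424242))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
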