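import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230531)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (5+5 subjects, 30 min sessions) for cheap
    integration tests; phenotype parameters stay at their defaults."""
    from dialhrv import CohortSpec, generate_cohort

    spec = CohortSpec(n_hs=5, n_hu=5, duration_s=1800.0, seed=99)
    return spec, generate_cohort(spec)
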