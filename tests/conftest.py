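import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2023)


@pytest.fixture(scope="session")
def small_survey():
    """2 countries x 120 persons, 6 items (mixed K), light missingness."""
    from scimetric.synthetic import SyntheticConfig, simulate

    cfg = SyntheticConfig(
        n_countries=2,
        n_per_country=[120, 120],
        n_items=6,
        categories_per_item=[2, 3, 4, 4, 5, 2],
        missing_rate_items=0.05,
        seed=11,
    )
    data, truth = simulate(cfg)
    return data, truth, cfg
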