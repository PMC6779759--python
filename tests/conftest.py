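import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elevcolour.synthetic import GeneratorConfig, generate_species_pool, render_specimen

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_species=12, images_per_species=(1, 2), seed=11)


@pytest.fixture(scope="session")
def rendered_specimens(small_config):
    """Ten deterministic (image, mask) renders of distinct species."""
    rng = np.random.default_rng(5)
    pool = generate_species_pool(small_config, rng)
    out = []
    for sp in pool[:10]:
        out.append(render_specimen(sp, sp.true_mean_elevation, rng, small_config))
    return out
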