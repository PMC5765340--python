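import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_genome():
    from gsrefresh.synthpop import GenomeSpec

    return GenomeSpec.default(
        n_chromosomes=2, n_markers_per_chrom=50, n_qtl_per_chrom=5
    )


@pytest.fixture(scope="session")
def tiny_founders(tiny_genome):
    """A small calibrated founder population shared across read-only tests."""
    from gsrefresh.synthpop import TraitModel, assign_trait, simulate_founders

    pop = simulate_founders(
        tiny_genome, 30, 30, n_burnin_generations=10, seed=99, burnin_size=60
    )
    trait = TraitModel.draw(tiny_genome, np.random.default_rng(7))
    trait = assign_trait(pop, trait, rescale=True)
    return pop, trait
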