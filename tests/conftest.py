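import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitorates as mr

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def poisson1():
    """Equal-rates model without rate heterogeneity."""
    return mr.poisson_model(alpha=1.0, n_categories=1)


@pytest.fixture(scope="session")
def poisson4():
    return mr.poisson_model(alpha=0.7, n_categories=4)


def small_study_config(seed=0, n_species=14, n_sites=600):
    """A reduced synthetic study: one accelerated mito-like category and one
    control, three haplodiploid clades."""
    mult = {"hymenoptera": 2.5, "haplo2": 2.5, "haplo3": 2.5}
    gene_len = n_sites // 3
    cats = [
        mr.CategorySpec("mtOXPHOS", 3, 0.0018, dict(mult),
                        mean_gene_length=gene_len),
        mr.CategorySpec("nucControl", 3, 0.00136, {},
                        mean_gene_length=gene_len),
    ]
    return mr.SimulationConfig(
        n_species=n_species,
        n_haplodiploid_clades=3,
        root_age=500.0,
        alpha=0.7,
        categories=cats,
        n_copy_families=20,
        biased_families=[
            mr.BiasSpec({"sawflies_wasps": 2, "bees_ants": 1}, n_families=4,
                        name="biasEFTu")
        ],
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_bundle():
    # 16 species / seed 11 gives a bees_ants vs sawflies_wasps split with at
    # least two species on each side, so every group contrast is defined
    return mr.simulate_study(small_study_config(seed=11, n_species=16))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
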