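import numpy as np
import pytest

from wingcpm import (
    CrossConfig,
    DominanceMechanism,
    example_alleles,
    simulate_cross_dataset,
)
from wingcpm.synth import NO_NOISE, NoiseModel


@pytest.fixture(scope="session")
def alleles():
    return example_alleles()


@pytest.fixture(scope="session")
def hierarchy_mech():
    return DominanceMechanism(kind="colour_hierarchy")


@pytest.fixture(scope="session")
def small_dataset(alleles, hierarchy_mech):
    """Two alleles, three individuals per genotype, 96 px, mild noise, no
    placement transforms — cheap ground-truth material for unit tests."""
    cfg = CrossConfig(
        alleles={k: alleles[k] for k in ("tar", "arc")},
        n_per_genotype=3,
        mechanism=hierarchy_mech,
        noise=NoiseModel(boundary_jitter_sd=0.8, colour_sd=6.0,
                         transform_ranges=(0.0, 0.0, (1.0, 1.0)),
                         pixel_noise_rate=0.001),
        resolution=96,
    )
    return simulate_cross_dataset(cfg, master_seed=11)


@pytest.fixture(scope="session")
def noise_free():
    return NO_NOISE


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
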