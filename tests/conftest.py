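"""Shared fixtures: small, seeded simulated systems."""

import numpy as np
import pytest

from polyforge.config import SimConfig
from polyforge.simulate import SimOutput, simulate_all


def small_config(**overrides) -> SimConfig:
    """Desk-scale config: 2 x 500 kb chromosome pairs, modest gene set."""
    base = dict(
        seed=11,
        n_chromosomes=2,
        chrom_length=500_000,
        gene_count=60,
        n_samples=4,
        n_segmental_he=2,
        n_balanced_he=1,
        n_nonreciprocal_he=1,
        n_genic_he=8,
        he_size_range=(15_000, 60_000),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim() -> SimOutput:
    return simulate_all(small_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
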