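"""Shared fixtures: small synthetic genomes kept cheap enough for unit tests."""

import numpy as np
import pytest

from subtadscope import synth
from subtadscope.contacts import ContactMatrix


@pytest.fixture(scope="session")
def small_genome() -> synth.GenomeSpec:
    return synth.GenomeSpec({"chrA": 8_000_000}, 10_000)


@pytest.fixture(scope="session")
def small_hierarchy(small_genome):
    return synth.generate_domain_hierarchy(small_genome, seed=11)


@pytest.fixture(scope="session")
def small_matrix(small_hierarchy):
    return synth.simulate_contact_matrix(small_hierarchy, "chrA", seed=12)


@pytest.fixture(scope="session")
def small_experiment(small_genome):
    """One full paired-condition experiment on the single-chromosome genome."""
    return synth.simulate_experiment(genome=small_genome, seed=21)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_symmetric_matrix(rng: np.random.Generator, n: int, chrom: str = "chrA",
                            resolution: int = 10_000) -> ContactMatrix:
    a = rng.poisson(8.0, size=(n, n)).astype(float)
    counts = np.triu(a) + np.triu(a, 1).T
    return ContactMatrix(chrom=chrom, resolution=resolution, counts=counts)
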