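"""Shared fixtures: small founder pools and populations built once per run."""

import numpy as np
import pytest

import resilsim as rs


@pytest.fixture(scope="session")
def mini_genome() -> rs.GenomeConfig:
    """Tiny, fast founder-genome configuration for unit tests."""
    return rs.GenomeConfig(n_chromosomes=2, n_loci=1500, mutation_rate=1e-4,
                           founder_size=30, burnin_generations=250,
                           expansion_generations=3, expanded_size=300)


@pytest.fixture(scope="session")
def mini_pool(mini_genome) -> rs.HaplotypePool:
    return rs.simulate_founder_pool(mini_genome, seed=1234)


@pytest.fixture(scope="session")
def desk_pool() -> rs.HaplotypePool:
    """Desk-scale founder pool shared by the heavier integration tests."""
    return rs.simulate_founder_pool(rs.GenomeConfig.desk(), seed=2024)


@pytest.fixture(scope="session")
def halfsib_population(mini_pool):
    """Base of 8 sires + 80 dams plus one half-sib offspring generation."""
    rng = np.random.default_rng(7)
    pop = rs.sample_base_population(mini_pool, 8, 80, rng)
    sires = np.repeat(np.arange(8), 10)
    dams = 8 + rng.permutation(80)
    sexes = np.tile([1, 2], 40).astype(np.int8)
    rs.make_offspring(pop, sires, dams, sexes, rng)
    return pop
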