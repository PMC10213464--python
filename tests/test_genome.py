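"""Founder-genome simulation, base sampling, and gene dropping."""

import numpy as np
import pytest

import resilsim as rs
from resilsim.genome import MALE, FEMALE, _alternating_sexes, _next_generation


def test_config_validation():
    with pytest.raises(ValueError):
        rs.GenomeConfig(mutation_rate=-0.1)
    with pytest.raises(ValueError):
        rs.GenomeConfig(n_loci=0)
    with pytest.raises(ValueError):
        rs.GenomeConfig(chrom_length=0.0)
    with pytest.raises(ValueError):
        rs.GenomeConfig(expanded_size=10, founder_size=100)


def test_zero_mutation_monomorphic_start_stays_monomorphic():
    cfg = rs.GenomeConfig(n_chromosomes=1, n_loci=200, mutation_rate=0.0,
                          founder_size=10, burnin_generations=20,
                          expansion_generations=2, expanded_size=20)
    pool = rs.simulate_founder_pool(cfg, seed=0)
    assert pool.segregating_counts().tolist() == [0]


def test_pool_only_segregating_and_positions_increasing(mini_pool):
    for chrom in mini_pool.chromosomes:
        freq = chrom.allele_frequencies()
        assert np.all(freq > 0) and np.all(freq < 1)
        assert np.all(np.diff(chrom.positions) > 0)
        assert chrom.positions[0] >= 0
        assert chrom.positions[-1] <= mini_pool.config.chrom_length
        assert chrom.n_haplotypes == 2 * mini_pool.config.expanded_size


def test_gamete_is_parental_copy_without_recombination():
    rng = np.random.default_rng(0)
    h = np.array([[0, 0, 0, 0], [1, 1, 1, 1]], dtype=np.uint8)
    pos = np.linspace(0, 1, 4)
    picks = [rs.drop_gamete(h, pos, 1e-12, np.random.default_rng(s))
             for s in range(200)]
    # each gamete equals exactly one parental haplotype; both occur
    kinds = {tuple(g) for g in picks}
    assert kinds == {(0, 0, 0, 0), (1, 1, 1, 1)}


def test_gamete_alleles_always_parental():
    rng = np.random.default_rng(3)
    h = rng.integers(0, 2, size=(2, 300)).astype(np.uint8)
    pos = np.sort(rng.uniform(0, 1, 300))
    for s in range(20):
        g = rs.drop_gamete(h, pos, 1.0, np.random.default_rng(s))
        assert np.all((g == h[0]) | (g == h[1]))


def test_haldane_recombinant_fraction_at_half_morgan():
    """Two loci 0.5 M apart recombine with frequency (1 - e^-1)/2 = 0.316."""
    h = np.array([[0, 0], [1, 1]], dtype=np.uint8)
    pos = np.array([0.25, 0.75])
    rng = np.random.default_rng(42)
    n = 40_000
    rec = sum(int(g[0] != g[1])
              for g in (rs.drop_gamete(h, pos, 1.0, rng) for _ in range(n)))
    expected = (1 - np.exp(-1)) / 2
    assert rec / n == pytest.approx(expected, abs=0.01)


def test_heterozygosity_decays_at_drift_rate_without_mutation():
    """E[2p(1-p)] shrinks by (1 - 1/(2N)) per generation of pure drift."""
    N, L, gens, reps = 16, 60, 8, 40
    pos = np.linspace(0, 1, L)
    ratios = []
    for s in range(reps):
        rng = np.random.default_rng(s)
        haps = rng.integers(0, 2, size=(2 * N, L)).astype(np.uint8)
        sexes = _alternating_sexes(N)
        h0 = np.mean(2 * haps.mean(0) * (1 - haps.mean(0)))
        for _ in range(gens):
            haps = _next_generation(haps, sexes, N, pos, 1.0, 0.0, rng)
        p = haps.mean(0)
        ratios.append(np.mean(2 * p * (1 - p)) / h0)
    expected = (1 - 1 / (2 * N)) ** gens
    assert np.mean(ratios) == pytest.approx(expected, rel=0.06)


def test_equilibrium_heterozygosity_matches_single_locus_oracle():
    """Genome-sim heterozygosity at mutation-drift equilibrium agrees with a
    scalar Wright-Fisher oracle run at the same N and mu."""
    N, mu, gens = 20, 1e-3, 400
    cfg = rs.GenomeConfig(n_chromosomes=2, n_loci=500, chrom_length=10.0,
                          mutation_rate=mu, founder_size=N,
                          burnin_generations=gens, expansion_generations=1,
                          expanded_size=N)
    # oracle: independent single-locus WF with symmetric flip mutation
    rng = np.random.default_rng(99)
    reps = 4000
    p = np.zeros(reps)
    for _ in range(gens):
        pm = p * (1 - mu) + (1 - p) * mu
        p = rng.binomial(2 * N, pm) / (2 * N)
    oracle_h = np.mean(2 * p * (1 - p))
    # simulator: average over all loci including those lost again
    ss = np.random.SeedSequence(5).spawn(cfg.n_chromosomes)
    hs = []
    from resilsim.genome import _simulate_chromosome
    for s in ss:
        chrom = _simulate_chromosome(cfg, np.random.default_rng(s))
        freq = chrom.allele_frequencies()
        h_seg = np.sum(2 * freq * (1 - freq))
        hs.append(h_seg / cfg.n_loci)  # lost loci contribute 0
    assert np.mean(hs) == pytest.approx(oracle_h, rel=0.35)


def test_base_sampling_counts_and_sexes(mini_pool):
    pop = rs.sample_base_population(mini_pool, 10, 30, seed=5)
    assert pop.n == 40
    assert (pop.sex == MALE).sum() == 10
    assert (pop.sex == FEMALE).sum() == 30
    assert np.all(pop.sire == -1) and np.all(pop.dam == -1)
    for c in range(pop.n_chromosomes):
        assert pop.haplotypes[c].shape[0] == 80


def test_base_sampling_without_replacement_exhausts_pool(mini_pool):
    n = mini_pool.n_haplotypes // 2
    pop = rs.sample_base_population(mini_pool, n // 2, n - n // 2, seed=8)
    for c, chrom in enumerate(mini_pool.chromosomes):
        # every pool haplotype used exactly once => same multiset of rows,
        # hence identical per-locus allele counts and per-row allele counts
        assert pop.haplotypes[c].shape == chrom.haplotypes.shape
        assert np.array_equal(pop.haplotypes[c].sum(axis=0),
                              chrom.haplotypes.sum(axis=0))
        assert np.array_equal(
            np.sort(pop.haplotypes[c].sum(axis=1)),
            np.sort(chrom.haplotypes.sum(axis=1)))


def test_base_sampling_overdraw_raises(mini_pool):
    n = mini_pool.n_haplotypes  # needs 2n haplotypes
    with pytest.raises(ValueError):
        rs.sample_base_population(mini_pool, n, n, seed=0)


def test_base_allele_frequencies_track_pool(mini_pool):
    pop = rs.sample_base_population(mini_pool, 50, 100, seed=3)
    chrom = mini_pool.chromosomes[0]
    pool_freq = chrom.allele_frequencies()
    base_freq = pop.dosages(0).mean(axis=0) / 2
    # sampling without replacement: tight agreement at this fraction
    assert np.max(np.abs(pool_freq - base_freq)) < 0.12
    assert np.corrcoef(pool_freq, base_freq)[0, 1] > 0.97


def test_gene_dropping_conserves_alleles(halfsib_population):
    pop = halfsib_population
    rng = np.random.default_rng(0)
    kids = np.flatnonzero(pop.generation == 1)
    for i in kids[:10]:
        s, d = pop.sire[i], pop.dam[i]
        for c in range(pop.n_chromosomes):
            kid = pop.haplotype_pair(i, c)
            sh = pop.haplotype_pair(s, c)
            dh = pop.haplotype_pair(d, c)
            assert np.all((kid[0] == sh[0]) | (kid[0] == sh[1]))
            assert np.all((kid[1] == dh[0]) | (kid[1] == dh[1]))


def test_make_offspring_rejects_wrong_sex_parents(mini_pool):
    pop = rs.sample_base_population(mini_pool, 2, 2, seed=0)
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        rs.make_offspring(pop, np.array([2]), np.array([3]),
                          np.array([1]), rng)  # individual 2 is female


def test_chromosomes_sampled_independently(mini_pool):
    """Allele-frequency draws on different chromosomes are uncorrelated."""
    f0, f1 = [], []
    for s in range(120):
        pop = rs.sample_base_population(mini_pool, 2, 2, seed=s)
        f0.append(pop.dosages(0)[:, 0].mean())
        f1.append(pop.dosages(1)[:, 0].mean())
    r = np.corrcoef(f0, f1)[0, 1]
    assert abs(r) < 0.3


def test_pedigree_frame_and_pool_roundtrip(mini_pool, halfsib_population,
                                           tmp_path):
    frame = halfsib_population.pedigree_frame()
    assert list(frame.columns) == ["id", "sire", "dam", "sex", "generation"]
    assert (frame.loc[frame.generation == 0, ["sire", "dam"]] == 0).all().all()
    path = tmp_path / "pool.h5"
    rs.save_pool(mini_pool, str(path))
    back = rs.load_pool(str(path))
    assert back.config == mini_pool.config
    for a, b in zip(back.chromosomes, mini_pool.chromosomes):
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.allclose(a.positions, b.positions)


def test_simulation_reproducible():
    cfg = rs.GenomeConfig(n_chromosomes=2, n_loci=300, mutation_rate=2e-4,
                          founder_size=10, burnin_generations=50,
                          expansion_generations=2, expanded_size=40)
    p1 = rs.simulate_founder_pool(cfg, seed=9)
    p2 = rs.simulate_founder_pool(cfg, seed=9)
    for a, b in zip(p1.chromosomes, p2.chromosomes):
        assert np.array_equal(a.haplotypes, b.haplotypes)
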