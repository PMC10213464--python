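"""Forward mutation-drift genome simulation and gene dropping.

Simulates a founder genome in linkage disequilibrium by letting a small
population of constant size drift to mutation-drift equilibrium, expanding it
to a large haplotype pool, and then sampling base populations / dropping
gametes through arbitrary pedigrees under Mendelian inheritance with Haldane
(no-interference) recombination.

Loci are biallelic (alleles coded 0/1), placed equidistantly on each
chromosome, and mutate by recurrent symmetric flips.  After the founder
simulation only segregating loci are retained; downstream gene dropping adds
no new mutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeConfig",
    "ChromosomePool",
    "HaplotypePool",
    "Population",
    "simulate_founder_pool",
    "sample_base_population",
    "drop_gamete",
    "make_offspring",
    "save_pool",
    "load_pool",
]

MALE = 1
FEMALE = 2
UNKNOWN = -1


@dataclass(frozen=True)
class GenomeConfig:
    """Parameters of the founder-genome simulation.

    Defaults describe a sheep-like genome: 26 autosomes of one Morgan each
    with 200,000 equidistant biallelic loci and a per-locus mutation rate of
    1e-5, evolved for 10,000 burn-in generations at N=100 and expanded to
    10,000 individuals over 5 generations.  ``desk()`` returns a reduced
    configuration with the per-locus scaled mutation pressure (4*N*mu)
    preserved, for fast desk-scale studies.
    """

    n_chromosomes: int = 26
    chrom_length: float = 1.0  # Morgan
    n_loci: int = 200_000
    mutation_rate: float = 1e-5
    founder_size: int = 100
    burnin_generations: int = 10_000
    expansion_generations: int = 5
    expanded_size: int = 10_000

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.n_loci, self.founder_size,
               self.expansion_generations, self.expanded_size) <= 0:
            raise ValueError("all counts must be positive")
        if self.burnin_generations < 0:
            raise ValueError("burnin_generations must be >= 0")
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be > 0")
        if self.expanded_size < self.founder_size:
            raise ValueError("expanded_size must be >= founder_size")

    @classmethod
    def desk(cls, n_chromosomes: int = 3, n_loci: int = 8_000,
             founder_size: int = 50, burnin_generations: int = 400,
             expanded_size: int = 1_000,
             theta_boost: float = 2.0) -> "GenomeConfig":
        # rescale mu so 4*N*mu per locus matches full scale, times a boost
        # that keeps enough segregating loci per chromosome for QTL/SNP-panel
        # selection on the much shorter desk genome
        full = cls()
        mu = full.mutation_rate * (full.founder_size / founder_size) \
            * theta_boost
        return cls(n_chromosomes=n_chromosomes, n_loci=n_loci,
                   mutation_rate=mu, founder_size=founder_size,
                   burnin_generations=burnin_generations,
                   expansion_generations=full.expansion_generations,
                   expanded_size=expanded_size)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GenomeConfig":
        return cls(**json.loads(text))


@dataclass
class ChromosomePool:
    """Haplotypes over the segregating loci of one chromosome."""

    haplotypes: np.ndarray  # (n_hap, n_seg) uint8 in {0,1}
    positions: np.ndarray   # (n_seg,) Morgan, strictly increasing

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class HaplotypePool:
    """Per-chromosome founder haplotype pools used to seed base populations."""

    chromosomes: list[ChromosomePool]
    config: GenomeConfig

    @property
    def n_haplotypes(self) -> int:
        return self.chromosomes[0].n_haplotypes

    def segregating_counts(self) -> np.ndarray:
        return np.array([c.n_loci for c in self.chromosomes])


@dataclass
class Population:
    """Pedigree plus phased genomes.

    Individuals are indexed 0..n-1 in pedigree order (parents precede
    offspring).  ``haplotypes[c]`` is a (2n, n_seg_c) uint8 array; individual
    ``i`` owns rows ``2i`` and ``2i+1``.
    """

    sire: np.ndarray        # int64, UNKNOWN for founders
    dam: np.ndarray
    sex: np.ndarray         # MALE / FEMALE
    generation: np.ndarray  # int64
    haplotypes: list[np.ndarray]
    positions: list[np.ndarray] = field(default_factory=list)
    chrom_length: float = 1.0

    @property
    def n(self) -> int:
        return self.sire.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return len(self.haplotypes)

    def individuals_of_generation(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.generation == g)

    def haplotype_pair(self, i: int, c: int) -> np.ndarray:
        return self.haplotypes[c][2 * i:2 * i + 2]

    def dosages(self, c: int, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele-1 counts per individual (n, n_loci) for chromosome c."""
        h = self.haplotypes[c]
        d = h[0::2].astype(np.int8) + h[1::2].astype(np.int8)
        return d if loci is None else d[:, loci]

    def pedigree_frame(self) -> pd.DataFrame:
        """Pedigree as a 5-column table with 1-based ids, 0 = unknown."""
        return pd.DataFrame({
            "id": np.arange(self.n) + 1,
            "sire": np.where(self.sire == UNKNOWN, 0, self.sire + 1),
            "dam": np.where(self.dam == UNKNOWN, 0, self.dam + 1),
            "sex": self.sex,
            "generation": self.generation,
        })


# ---------------------------------------------------------------------------
# meiosis

def _meiosis(parent_haps: np.ndarray, positions: np.ndarray,
             chrom_length: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a (2, L) parental haplotype pair.

    Crossover count ~ Poisson(chrom_length), positions uniform on the map,
    starting strand chosen with probability 1/2 (Haldane model).
    """
    start = int(rng.integers(2))
    k = int(rng.poisson(chrom_length))
    if k == 0 or parent_haps.shape[1] == 0:
        return parent_haps[start].copy()
    cuts = np.sort(rng.uniform(0.0, chrom_length, size=k))
    # strand of each locus = start + #crossovers at positions < locus, mod 2
    strand = (start + np.searchsorted(cuts, positions, side="right")) % 2
    return parent_haps[strand, np.arange(parent_haps.shape[1])]


def drop_gamete(parent_haps: np.ndarray, positions: np.ndarray,
                chrom_length: float,
                rng: np.random.Generator | int) -> np.ndarray:
    """Public Mendelian gene-dropping primitive for one chromosome."""
    if parent_haps.ndim != 2 or parent_haps.shape[0] != 2:
        raise ValueError("parent_haps must have shape (2, n_loci)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _meiosis(parent_haps, positions, chrom_length, rng)


# ---------------------------------------------------------------------------
# founder simulation

def _next_generation(haps: np.ndarray, sexes: np.ndarray, n_next: int,
                     positions: np.ndarray, chrom_length: float,
                     mutation_rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Random union of gametes with separate sexes; recurrent flip mutation."""
    males = np.flatnonzero(sexes == MALE)
    females = np.flatnonzero(sexes == FEMALE)
    sires = rng.choice(males, size=n_next)
    dams = rng.choice(females, size=n_next)
    L = haps.shape[1]
    out = np.empty((2 * n_next, L), dtype=np.uint8)
    for i in range(n_next):
        out[2 * i] = _meiosis(haps[2 * sires[i]:2 * sires[i] + 2],
                              positions, chrom_length, rng)
        out[2 * i + 1] = _meiosis(haps[2 * dams[i]:2 * dams[i] + 2],
                                  positions, chrom_length, rng)
    if mutation_rate > 0 and L > 0:
        n_mut = rng.binomial(out.size, mutation_rate)
        if n_mut:
            flat = rng.integers(0, out.size, size=n_mut)
            out.reshape(-1)[flat] ^= 1
    return out


def _alternating_sexes(n: int) -> np.ndarray:
    sexes = np.empty(n, dtype=np.int8)
    sexes[0::2] = MALE
    sexes[1::2] = FEMALE
    return sexes


def _simulate_chromosome(config: GenomeConfig,
                         rng: np.random.Generator) -> ChromosomePool:
    L = config.n_loci
    positions = np.linspace(0.0, config.chrom_length, num=L) if L > 1 \
        else np.array([config.chrom_length / 2])
    n = config.founder_size
    haps = np.zeros((2 * n, L), dtype=np.uint8)  # monomorphic start
    sexes = _alternating_sexes(n)
    for _ in range(config.burnin_generations):
        haps = _next_generation(haps, sexes, n, positions,
                                config.chrom_length, config.mutation_rate,
                                rng)
    # exponential expansion to the pool size
    growth = (config.expanded_size / config.founder_size) ** (
        1.0 / config.expansion_generations)
    size = config.founder_size
    for g in range(config.expansion_generations):
        nxt = config.expanded_size if g == config.expansion_generations - 1 \
            else int(round(config.founder_size * growth ** (g + 1)))
        haps = _next_generation(haps, sexes, nxt, positions,
                                config.chrom_length, config.mutation_rate,
                                rng)
        size = nxt
        sexes = _alternating_sexes(size)
    counts = haps.sum(axis=0, dtype=np.int64)
    seg = np.flatnonzero((counts > 0) & (counts < haps.shape[0]))
    return ChromosomePool(haplotypes=np.ascontiguousarray(haps[:, seg]),
                          positions=positions[seg])


def simulate_founder_pool(config: GenomeConfig, seed: int) -> HaplotypePool:
    """Run burn-in + expansion and return the segregating-locus pool.

    Chromosomes are simulated on independent child RNG streams spawned from
    ``seed``, so they are mutually independent and individually reproducible.
    """
    streams = np.random.SeedSequence(seed).spawn(config.n_chromosomes)
    chroms = [_simulate_chromosome(config, np.random.default_rng(s))
              for s in streams]
    return HaplotypePool(chromosomes=chroms, config=config)


# ---------------------------------------------------------------------------
# base population and pedigree growth

def sample_base_population(pool: HaplotypePool, n_males: int, n_females: int,
                           seed: int | np.random.Generator) -> Population:
    """Draw a founder generation from the pool.

    Haplotypes are drawn without replacement within a chromosome and
    independently across chromosomes.  Males come first in the index order.
    """
    n = n_males + n_females
    if 2 * n > pool.n_haplotypes:
        raise ValueError(
            f"requested {2 * n} haplotypes, pool has {pool.n_haplotypes}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    haps = []
    for chrom in pool.chromosomes:
        idx = rng.choice(chrom.n_haplotypes, size=2 * n, replace=False)
        haps.append(np.ascontiguousarray(chrom.haplotypes[idx]))
    sex = np.concatenate([np.full(n_males, MALE, dtype=np.int8),
                          np.full(n_females, FEMALE, dtype=np.int8)])
    return Population(
        sire=np.full(n, UNKNOWN, dtype=np.int64),
        dam=np.full(n, UNKNOWN, dtype=np.int64),
        sex=sex,
        generation=np.zeros(n, dtype=np.int64),
        haplotypes=haps,
        positions=[c.positions for c in pool.chromosomes],
        chrom_length=pool.config.chrom_length,
    )


def make_offspring(pop: Population, sires: np.ndarray, dams: np.ndarray,
                   sexes: np.ndarray, rng: np.random.Generator,
                   generation: int | None = None) -> np.ndarray:
    """Append offspring produced by gamete dropping; returns their indices.

    ``sires[i]`` / ``dams[i]`` are parent indices of offspring ``i``.  Sexes
    are assigned as given.  No new mutations are introduced.
    """
    sires = np.asarray(sires, dtype=np.int64)
    dams = np.asarray(dams, dtype=np.int64)
    sexes = np.asarray(sexes, dtype=np.int8)
    if not (np.all(pop.sex[sires] == MALE) and np.all(pop.sex[dams] == FEMALE)):
        raise ValueError("sires must be male and dams female")
    m = sires.shape[0]
    start = pop.n
    if generation is None:
        generation = int(pop.generation[sires].max()) + 1
    for c in range(pop.n_chromosomes):
        old = pop.haplotypes[c]
        new = np.empty((2 * m, old.shape[1]), dtype=np.uint8)
        pos, clen = pop.positions[c], pop.chrom_length
        for i in range(m):
            new[2 * i] = _meiosis(old[2 * sires[i]:2 * sires[i] + 2],
                                  pos, clen, rng)
            new[2 * i + 1] = _meiosis(old[2 * dams[i]:2 * dams[i] + 2],
                                      pos, clen, rng)
        pop.haplotypes[c] = np.vstack([old, new])
    pop.sire = np.concatenate([pop.sire, sires])
    pop.dam = np.concatenate([pop.dam, dams])
    pop.sex = np.concatenate([pop.sex, sexes])
    pop.generation = np.concatenate(
        [pop.generation, np.full(m, generation, dtype=np.int64)])
    return np.arange(start, start + m)


# ---------------------------------------------------------------------------
# serialization

def save_pool(pool: HaplotypePool, path: str) -> None:
    """Store the pool in an HDF5 container with a JSON config attribute."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config"] = pool.config.to_json()
        for i, chrom in enumerate(pool.chromosomes):
            g = f.create_group(f"chromosome_{i:02d}")
            g.create_dataset("haplotypes", data=np.packbits(
                chrom.haplotypes, axis=1), compression="gzip")
            g.attrs["n_loci"] = chrom.n_loci
            g.create_dataset("positions", data=chrom.positions)


def load_pool(path: str) -> HaplotypePool:
    import h5py

    with h5py.File(path, "r") as f:
        config = GenomeConfig.from_json(f.attrs["config"])
        chroms = []
        for name in sorted(k for k in f if k.startswith("chromosome_")):
            g = f[name]
            n_loci = int(g.attrs["n_loci"])
            haps = np.unpackbits(g["haplotypes"][...], axis=1)[:, :n_loci]
            chroms.append(ChromosomePool(haplotypes=haps,
                                         positions=g["positions"][...]))
    return HaplotypePool(chromosomes=chroms, config=config)
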