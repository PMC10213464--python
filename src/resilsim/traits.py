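"""Genetic architecture of production potential and resilience.

Two traits drive a linear reaction norm: the intercept A0 (production
potential, performance at zero challenge) and the slope AR (resilience,
change of performance per unit of environmental challenge).  Both are
controlled by the same pleiotropic QTL whose effects are drawn from a
standard bivariate normal with the target genetic correlation and then
rescaled so that the variances of the true breeding values in the base
generation hit the target variances exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Population

__all__ = [
    "TraitParams",
    "TraitArchitecture",
    "TrueBreedingValues",
    "select_loci",
    "sample_qtl_effects",
    "compute_tbv",
]


@dataclass(frozen=True)
class TraitParams:
    """Population parameters of the reaction-norm trait model.

    ``mu0`` is the mean performance at zero challenge, ``muR`` the mean slope
    (negative: challenge depresses performance).  Genetic (co)variances refer
    to base-generation TBVs; ``var_e0`` / ``var_er`` are per-record residual
    variances of intercept and slope deviations.
    """

    mu0: float = 10.0
    muR: float = -3.0
    var_a0: float = 0.1
    var_ar: float = 0.1
    rho_a: float = -0.5
    var_e0: float = 0.9
    var_er: float = 0.9

    def __post_init__(self) -> None:
        if min(self.var_a0, self.var_ar, self.var_e0, self.var_er) < 0:
            raise ValueError("variances must be non-negative")
        if abs(self.rho_a) > 1:
            raise ValueError("|rho_a| must be <= 1")

    @property
    def cov_a(self) -> float:
        return self.rho_a * np.sqrt(self.var_a0 * self.var_ar)

    @property
    def genetic_covariance(self) -> np.ndarray:
        return np.array([[self.var_a0, self.cov_a],
                         [self.cov_a, self.var_ar]])


@dataclass
class TraitArchitecture:
    """QTL / SNP-panel locus indices and scaled pleiotropic QTL effects.

    Locus indices refer to columns of the population's per-chromosome
    segregating-locus arrays.  ``qtl_effects`` stacks per-chromosome QTL in
    chromosome order; column 0 acts on A0, column 1 on AR.  ``tbv_offset``
    centres TBVs on the base-generation mean (the population mean is carried
    by mu0/muR, not by the TBVs).
    """

    qtl_loci: list[np.ndarray]
    snp_loci: list[np.ndarray]
    qtl_effects: np.ndarray | None = None
    scaling: np.ndarray | None = None
    tbv_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def n_qtl(self) -> int:
        return int(sum(len(q) for q in self.qtl_loci))

    @property
    def n_snp(self) -> int:
        return int(sum(len(s) for s in self.snp_loci))


@dataclass
class TrueBreedingValues:
    a0: np.ndarray
    ar: np.ndarray


def _maf(dosages: np.ndarray) -> np.ndarray:
    p = dosages.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def select_loci(base: Population, per_chrom_top: int = 1500,
                n_qtl: int = 500, n_snp: int = 1000,
                seed: int | np.random.Generator = 0) -> TraitArchitecture:
    """Pick QTL and SNP-panel loci per chromosome.

    The ``per_chrom_top`` segregating loci with the highest minor allele
    frequency (ties broken by locus index, so the choice is deterministic
    given the seed) are split at random into disjoint QTL and SNP sets.
    """
    if n_qtl + n_snp > per_chrom_top:
        raise ValueError("n_qtl + n_snp must not exceed per_chrom_top")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    base_idx = base.individuals_of_generation(0)
    qtl_loci, snp_loci = [], []
    for c in range(base.n_chromosomes):
        dos = base.dosages(c)[base_idx]
        maf = _maf(dos)
        seg = np.flatnonzero(maf > 0)
        if seg.size < per_chrom_top:
            raise ValueError(
                f"chromosome {c}: only {seg.size} segregating loci, "
                f"need {per_chrom_top}; simulate a denser genome")
        # stable sort on -maf keeps index order within ties
        top = seg[np.argsort(-maf[seg], kind="stable")[:per_chrom_top]]
        perm = rng.permutation(per_chrom_top)
        qtl_loci.append(np.sort(top[perm[:n_qtl]]))
        snp_loci.append(np.sort(top[perm[n_qtl:n_qtl + n_snp]]))
    return TraitArchitecture(qtl_loci=qtl_loci, snp_loci=snp_loci)


def _raw_tbv(pop: Population, arch: TraitArchitecture,
             effects: np.ndarray) -> np.ndarray:
    tbv = np.zeros((pop.n, 2))
    row = 0
    for c in range(pop.n_chromosomes):
        q = arch.qtl_loci[c]
        tbv += pop.dosages(c, q).astype(np.float64) @ effects[row:row + q.size]
        row += q.size
    return tbv


def sample_qtl_effects(arch: TraitArchitecture, params: TraitParams,
                       base: Population,
                       seed: int | np.random.Generator = 0
                       ) -> TraitArchitecture:
    """Draw bivariate-normal QTL effects and rescale to target variances.

    Raw effects have unit variance and correlation rho_a; each column is then
    multiplied by a factor making the empirical base-generation TBV variance
    equal the target exactly.  TBVs are subsequently reported as deviations
    from the base mean.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    corr = np.array([[1.0, params.rho_a], [params.rho_a, 1.0]])
    chol = np.linalg.cholesky(corr)
    raw = rng.standard_normal((arch.n_qtl, 2)) @ chol.T
    base_idx = base.individuals_of_generation(0)
    tbv = _raw_tbv(base, arch, raw)[base_idx]
    emp_var = tbv.var(axis=0)
    if np.any(emp_var <= 0):
        raise ValueError("degenerate genome: zero TBV variance before scaling")
    scaling = np.sqrt(np.array([params.var_a0, params.var_ar]) / emp_var)
    arch.qtl_effects = raw * scaling
    arch.scaling = scaling
    arch.tbv_offset = (tbv * scaling).mean(axis=0)
    return arch


def compute_tbv(pop: Population, arch: TraitArchitecture) -> TrueBreedingValues:
    """Dosage-weighted QTL effect sums, centred on the base-generation mean."""
    if arch.qtl_effects is None:
        raise ValueError("QTL effects have not been sampled")
    tbv = _raw_tbv(pop, arch, arch.qtl_effects) - arch.tbv_offset
    return TrueBreedingValues(a0=tbv[:, 0], ar=tbv[:, 1])


def snp_dosage_matrix(pop: Population, arch: TraitArchitecture,
                      individuals: np.ndarray | None = None) -> np.ndarray:
    """SNP-panel dosage matrix (individuals x SNPs), chromosome-major order."""
    blocks = [pop.dosages(c, arch.snp_loci[c]).astype(np.float64)
              for c in range(pop.n_chromosomes)]
    m = np.hstack(blocks)
    return m if individuals is None else m[individuals]


def snp_map(pop: Population, arch: TraitArchitecture) -> "pd.DataFrame":
    """Locus map of the SNP panel: chromosome, index, position, MAF."""
    import pandas as pd

    rows = []
    for c in range(pop.n_chromosomes):
        loci = arch.snp_loci[c]
        maf = _maf(pop.dosages(c, loci))
        rows.append(pd.DataFrame({
            "chromosome": c, "locus": loci,
            "position": pop.positions[c][loci], "maf": maf}))
    return pd.concat(rows, ignore_index=True)
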