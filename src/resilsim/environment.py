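"""Flock-structured environmental challenge and phenotype simulation.

Animals are phenotyped in flocks: contemporary groups whose mean challenge
level is drawn uniformly from the overall challenge range shrunk by half a
flock width at each end, so that every record's challenge stays inside the
overall range.  Within a flock, each record's challenge is uniform on an
interval of width Xmax * epsilon around the flock mean.  Phenotypes follow
the linear reaction norm

    y = mu0 + A0 + E0 + X * (muR + AR + ER)

with independent per-record residuals E0 ~ N(0, var_e0), ER ~ N(0, var_er).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import UNKNOWN, Population
from .traits import TraitParams, TrueBreedingValues

__all__ = [
    "EnvConfig",
    "FlockAssignment",
    "sample_flock_means",
    "allocate_individuals",
    "sample_record_challenges",
    "simulate_phenotypes",
]

ALLOCATIONS = ("RND", "CLS", "AST", "DIS")


@dataclass(frozen=True)
class EnvConfig:
    """Challenge-range geometry and flock layout.

    ``x_range`` is the overall challenge interval (wide default [0, 2];
    narrow studies use [0, 1] or [1, 2]); ``xmax`` is the scale constant that
    with epsilon fixes the within-flock width Xmax*epsilon.  ``epsilon`` is
    the flock heterogeneity relative to the full scale.
    """

    x_range: tuple[float, float] = (0.0, 2.0)
    xmax: float = 2.0
    n_flocks: int = 10
    epsilon: float = 0.1
    allocation: str = "RND"
    n_records: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.x_range
        if not (0 <= lo < hi <= self.xmax):
            raise ValueError("x_range must be within [0, xmax] and non-empty")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if self.n_flocks < 1 or self.n_records < 1:
            raise ValueError("n_flocks and n_records must be >= 1")
        if self.allocation not in ALLOCATIONS:
            raise ValueError(f"allocation must be one of {ALLOCATIONS}")

    @property
    def half_width(self) -> float:
        return self.xmax * self.epsilon / 2.0


@dataclass
class FlockAssignment:
    """Flock means, per-individual flock ids, and per-record challenges."""

    flock_means: np.ndarray          # (n_flocks,)
    individuals: np.ndarray          # indices into the population
    flock_of: np.ndarray             # (n_ind,) flock id per individual
    x: np.ndarray | None = None      # (n_ind, n_records) true challenge


def sample_flock_means(env: EnvConfig,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform flock means on the challenge range shrunk by a half width."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lo, hi = env.x_range
    a, b = lo + env.half_width, hi - env.half_width
    if a > b:
        raise ValueError("epsilon too large for the challenge range")
    return rng.uniform(a, b, size=env.n_flocks) if a < b \
        else np.full(env.n_flocks, a)


def _family_blocks(order: np.ndarray, n_flocks: int) -> np.ndarray:
    """Map family ranks to flock indices in contiguous, even blocks."""
    n_fam = order.shape[0]
    ranks = np.empty(n_fam, dtype=np.int64)
    ranks[order] = np.arange(n_fam)
    return (ranks * n_flocks) // n_fam


def allocate_individuals(pop: Population, individuals: np.ndarray,
                         tbv: TrueBreedingValues, flock_means: np.ndarray,
                         scheme: str,
                         seed: int | np.random.Generator = 0) -> FlockAssignment:
    """Assign each phenotyped individual to a flock.

    RND: individual-level uniform draw.  CLS: one uniform flock per paternal
    half-sib family.  AST: sires ranked by true A0 descending are paired with
    flocks ranked by mean challenge ascending (best families, best
    environments), in contiguous rank blocks when families outnumber flocks.
    DIS: AST with the sire order reversed.  Founders without a recorded sire
    are allocated uniformly at random under every scheme.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    individuals = np.asarray(individuals)
    n_flocks = flock_means.shape[0]
    flock_of = np.empty(individuals.shape[0], dtype=np.int64)
    sires = pop.sire[individuals]
    has_fam = sires != UNKNOWN
    flock_of[~has_fam] = rng.integers(n_flocks, size=int((~has_fam).sum()))
    if scheme == "RND":
        flock_of[:] = rng.integers(n_flocks, size=individuals.shape[0])
    elif has_fam.any():
        fam_sires, fam_code = np.unique(sires[has_fam], return_inverse=True)
        if scheme == "CLS":
            fam_flock = rng.integers(n_flocks, size=fam_sires.shape[0])
        elif scheme in ("AST", "DIS"):
            sire_a0 = tbv.a0[fam_sires]
            order = np.argsort(-sire_a0, kind="stable")  # best sire first
            if scheme == "DIS":
                order = order[::-1]
            blocks = _family_blocks(order, n_flocks)
            flocks_by_challenge = np.argsort(flock_means, kind="stable")
            fam_flock = flocks_by_challenge[blocks]
        else:
            raise ValueError(f"unknown allocation scheme {scheme!r}")
        flock_of[has_fam] = fam_flock[fam_code]
    return FlockAssignment(flock_means=flock_means, individuals=individuals,
                           flock_of=flock_of)


def sample_record_challenges(assign: FlockAssignment, env: EnvConfig,
                             seed: int | np.random.Generator = 0
                             ) -> FlockAssignment:
    """Draw one uniform challenge per record inside each flock's interval."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    centre = assign.flock_means[assign.flock_of][:, None]
    shape = (assign.individuals.shape[0], env.n_records)
    assign.x = centre + rng.uniform(-env.half_width, env.half_width,
                                    size=shape)
    return assign


def simulate_phenotypes(pop: Population, tbv: TrueBreedingValues,
                        params: TraitParams, assign: FlockAssignment,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Reaction-norm phenotypes for every record of the assignment.

    Returns a table with columns animal (population index), flock, record,
    x (true challenge) and y (observed performance).
    """
    if assign.x is None:
        raise ValueError("record challenges have not been sampled")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_ind, n_rec = assign.x.shape
    a0 = tbv.a0[assign.individuals][:, None]
    ar = tbv.ar[assign.individuals][:, None]
    e0 = rng.normal(0.0, np.sqrt(params.var_e0), size=(n_ind, n_rec))
    er = rng.normal(0.0, np.sqrt(params.var_er), size=(n_ind, n_rec))
    x = assign.x
    y = params.mu0 + a0 + e0 + x * (params.muR + ar + er)
    return pd.DataFrame({
        "animal": np.repeat(assign.individuals, n_rec),
        "flock": np.repeat(assign.flock_of, n_rec),
        "record": np.tile(np.arange(n_rec), n_ind),
        "x": x.reshape(-1),
        "y": y.reshape(-1),
    })
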