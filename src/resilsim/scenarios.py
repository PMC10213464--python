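"""Study configuration, replication, presets, and result tables.

Two study designs are provided.  The random-selection design (three
non-overlapping half-sib generations, the last one unphenotyped) measures
prediction accuracy and standardized bias of (G)EBVs for production
potential and resilience under different evaluation modes, record counts,
allocation schemes and challenge-knowledge assumptions.  The selection
design runs the multi-generation breeding scheme and reports genetic-gain
trajectories.

Presets mirror the experiments of the simulation study's figure panels at
full scale and offer tenth-scale ``desk`` variants for quick runs; the full
presets take hours per scenario on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .environment import (EnvConfig, allocate_individuals,
                          sample_flock_means, sample_record_challenges,
                          simulate_phenotypes)
from .evaluation import reml_rn, solve_blup_rn, two_step_evaluation
from .genome import FEMALE, MALE, GenomeConfig, HaplotypePool, Population, \
    make_offspring, sample_base_population, simulate_founder_pool
from .metrics import ReplicateMetrics, accuracy, aggregate, standardized_bias
from .relationships import build_grm, build_nrm
from .selection import SelectionConfig, run_selection_experiment
from .traits import TraitParams, compute_tbv, sample_qtl_effects, \
    select_loci, snp_dosage_matrix

__all__ = [
    "RandomDesign",
    "Cell",
    "ScenarioConfig",
    "build_three_generation_population",
    "run_random_replicate",
    "run_scenario",
    "list_presets",
    "get_preset",
]


@dataclass(frozen=True)
class RandomDesign:
    """Three-generation half-sib design under random selection.

    Generation 0: base males and females; each male is mated to
    ``g1_dams_per_sire`` dams (one offspring each, 1 male and the rest
    female per family).  Generation 1 males are each mated to
    ``g2_dams_per_sire`` generation-1 dams to produce the final, unphenotyped
    generation whose (G)EBVs are assessed.
    """

    n_base_males: int = 100
    n_base_females: int = 1100
    g1_dams_per_sire: int = 11
    g2_dams_per_sire: int = 10
    phenotyped_generations: tuple[int, ...] = (0, 1)
    per_chrom_top: int = 1500
    n_qtl: int = 500
    n_snp: int = 1000
    grm_diag_boost: float = 0.01

    @classmethod
    def desk(cls, **overrides) -> "RandomDesign":
        base = dict(n_base_males=10, n_base_females=110,
                    per_chrom_top=450, n_qtl=150, n_snp=300)
        base.update(overrides)
        return cls(**base)


def build_three_generation_population(pool: HaplotypePool,
                                      design: RandomDesign,
                                      rng: np.random.Generator) -> Population:
    """Sample the base generation and drop gametes through two matings."""
    pop = sample_base_population(pool, design.n_base_males,
                                 design.n_base_females, rng)
    males0 = np.arange(design.n_base_males)
    females0 = design.n_base_males + np.arange(design.n_base_females)
    # generation 1: one offspring per dam; 1 male then females per family
    dams = rng.permutation(females0)[
        :design.n_base_males * design.g1_dams_per_sire]
    sires = np.repeat(males0, design.g1_dams_per_sire)
    fam_sex = np.concatenate([[MALE],
                              np.full(design.g1_dams_per_sire - 1, FEMALE)])
    sexes = np.tile(fam_sex, design.n_base_males).astype(np.int8)
    gen1 = make_offspring(pop, sires, dams, sexes, rng, generation=1)
    males1 = gen1[pop.sex[gen1] == MALE]
    females1 = gen1[pop.sex[gen1] == FEMALE]
    dams2 = rng.permutation(females1)[
        :males1.size * design.g2_dams_per_sire]
    sires2 = np.repeat(males1, design.g2_dams_per_sire)
    sexes2 = np.tile(
        np.concatenate([[MALE], np.full(design.g2_dams_per_sire - 1,
                                        FEMALE)]),
        males1.size).astype(np.int8)
    make_offspring(pop, sires2, dams2, sexes2, rng, generation=2)
    return pop


@dataclass(frozen=True)
class Cell:
    """One scenario cell of a random-selection study."""

    label: str
    relationship: str = "grm"       # "grm" | "nrm"
    x_source: str = "known"         # "known" | "two_step"
    allocation: str = "RND"
    n_records: int = 3
    rho_a: float = -0.5
    epsilon: float = 0.1
    x_range: tuple[float, float] = (0.0, 2.0)


@dataclass
class ScenarioConfig:
    """A full study: design, trait/environment parameters, cells, seeds."""

    name: str
    kind: str                        # "random" | "selection"
    genome: GenomeConfig
    params: TraitParams = field(default_factory=TraitParams)
    design: RandomDesign = field(default_factory=RandomDesign)
    cells: list[Cell] = field(default_factory=list)
    selection: list[SelectionConfig] = field(default_factory=list)
    selection_env: list[EnvConfig] = field(default_factory=list)
    n_replicates: int = 100
    scale: str = "full"


def run_random_replicate(pool: HaplotypePool, design: RandomDesign,
                         params: TraitParams, cells: list[Cell],
                         seed: int | np.random.SeedSequence
                         ) -> list[ReplicateMetrics]:
    """One replicate of the random-selection design across scenario cells.

    The population, architecture and relationship matrices are shared by all
    cells; phenotypes are redrawn per cell (records, allocation, epsilon and
    challenge range are cell properties).  Metrics are computed on the
    unphenotyped final generation.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng_ped, rng_arch, rng_env = (np.random.default_rng(s)
                                  for s in ss.spawn(3))
    pop = build_three_generation_population(pool, design, rng_ped)
    target = pop.individuals_of_generation(2)
    phenotyped = np.concatenate(
        [pop.individuals_of_generation(g)
         for g in design.phenotyped_generations])
    nrm = build_nrm(pop.sire, pop.dam)
    out: list[ReplicateMetrics] = []
    # one architecture (and GRM) per replicate and genetic correlation, so
    # cells sharing a correlation are compared on paired genetic material
    arch_cache: dict[float, tuple] = {}
    for cell in cells:
        params_c = dataclasses.replace(params, rho_a=cell.rho_a)
        if cell.rho_a not in arch_cache:
            arch = select_loci(pop, per_chrom_top=design.per_chrom_top,
                               n_qtl=design.n_qtl, n_snp=design.n_snp,
                               seed=rng_arch)
            arch = sample_qtl_effects(arch, params_c, pop, rng_arch)
            grm = build_grm(snp_dosage_matrix(pop, arch)).stabilized(
                design.grm_diag_boost)
            arch_cache[cell.rho_a] = (arch, compute_tbv(pop, arch), grm)
        arch, tbv, grm = arch_cache[cell.rho_a]
        env = EnvConfig(x_range=cell.x_range, n_flocks=10,
                        epsilon=cell.epsilon, allocation=cell.allocation,
                        n_records=cell.n_records)
        flocks = sample_flock_means(env, rng_env)
        assign = allocate_individuals(pop, phenotyped, tbv, flocks,
                                      cell.allocation, rng_env)
        assign = sample_record_challenges(assign, env, rng_env)
        pheno = simulate_phenotypes(pop, tbv, params_c, assign, rng_env)
        K = nrm if cell.relationship == "nrm" else grm
        animal = pheno["animal"].to_numpy()
        y = pheno["y"].to_numpy()
        if cell.x_source == "two_step":
            res = two_step_evaluation(y, pheno["flock"].to_numpy(), animal,
                                      K, xmax=env.xmax)
            vc, ebv = res.vc, res.ebv
        else:
            vc = reml_rn(y, pheno["x"].to_numpy(), animal, K)
            ebv = solve_blup_rn(y, pheno["x"].to_numpy(), animal, K, vc)
        m = ReplicateMetrics(converged=bool(vc.feasible), subset=cell.label)
        if vc.feasible:
            m.accuracy_a0 = accuracy(ebv.a0_hat[target], tbv.a0[target])
            m.accuracy_ar = accuracy(ebv.ar_hat[target], tbv.ar[target])
            try:
                m.bias_a0 = standardized_bias(ebv.a0_hat[target],
                                              tbv.a0[target])
                m.bias_ar = standardized_bias(ebv.ar_hat[target],
                                              tbv.ar[target])
            except ValueError:
                pass  # non-positive slope: bias undefined, left NaN
        out.append(m)
    return out


def run_scenario(config: ScenarioConfig, seed: int,
                 out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Execute a study: replicate loop, aggregation, optional CSV output.

    Returns ``{"replicates": ..., "summary": ...}`` for random designs and
    ``{"trajectories": ..., "summary": ...}`` for selection designs.  With
    ``out_dir`` the tables are written as CSV along with a JSON provenance
    record (config, seed, package version).
    """
    ss = np.random.SeedSequence(seed)
    pool_seed, *rep_seeds = ss.spawn(config.n_replicates + 1)
    pool = simulate_founder_pool(config.genome,
                                 int(pool_seed.generate_state(1)[0] // 2))
    tables: dict[str, pd.DataFrame] = {}
    if config.kind == "random":
        rows = []
        for rep, rs in enumerate(rep_seeds):
            for m in run_random_replicate(pool, config.design, config.params,
                                          config.cells, rs):
                rows.append({"replicate": rep, "cell": m.subset,
                             "accuracy_a0": m.accuracy_a0,
                             "accuracy_ar": m.accuracy_ar,
                             "bias_a0": m.bias_a0, "bias_ar": m.bias_ar,
                             "converged": m.converged})
        reps = pd.DataFrame(rows)
        summaries = []
        for label, grp in reps.groupby("cell"):
            ms = [ReplicateMetrics(r.accuracy_a0, r.accuracy_ar, r.bias_a0,
                                   r.bias_ar, r.converged, label)
                  for r in grp.itertuples()]
            s = aggregate(ms)
            s.insert(0, "cell", label)
            summaries.append(s)
        tables["replicates"] = reps
        tables["summary"] = pd.concat(summaries, ignore_index=True)
    elif config.kind == "selection":
        trajs = []
        for rep, rs in enumerate(rep_seeds):
            sub = rs.spawn(len(config.selection))
            for scfg, senv, s in zip(config.selection, config.selection_env,
                                     sub):
                t = run_selection_experiment(
                    pool, scfg, config.params, senv,
                    int(s.generate_state(1)[0] // 2))
                t.insert(0, "replicate", rep)
                t.insert(1, "x_range", f"{senv.x_range}")
                trajs.append(t)
        traj = pd.concat(trajs, ignore_index=True)
        last = traj.groupby(["criterion", "alpha", "x_range"], as_index=False) \
            .apply(lambda g: pd.Series({
                "gain_a0": g.loc[g.generation == g.generation.max(),
                                 "mean_a0"].mean()
                - g.loc[g.generation == 1, "mean_a0"].mean(),
                "gain_ar": g.loc[g.generation == g.generation.max(),
                                 "mean_ar"].mean()
                - g.loc[g.generation == 1, "mean_ar"].mean(),
            }), include_groups=False)
        tables["trajectories"] = traj
        tables["summary"] = last
    else:
        raise ValueError(f"unknown study kind {config.kind!r}")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{config.name}_{name}.csv", index=False)
        prov = {"name": config.name, "kind": config.kind, "seed": seed,
                "n_replicates": config.n_replicates, "scale": config.scale,
                "version": __version__,
                "genome": config.genome.__dict__,
                "params": config.params.__dict__}
        (out / f"{config.name}_provenance.json").write_text(
            json.dumps(prov, indent=2, default=str))
    return tables


# ---------------------------------------------------------------------------
# presets

def _genome(scale: str) -> GenomeConfig:
    return GenomeConfig() if scale == "full" else GenomeConfig.desk()

def _design(scale: str) -> RandomDesign:
    return RandomDesign() if scale == "full" else RandomDesign.desk()

def _nrep(scale: str) -> int:
    return 100 if scale == "full" else 10


def _fig1(scale: str) -> ScenarioConfig:
    cells = [Cell(label=f"{rel}_records{n}", relationship=rel, n_records=n)
             for rel in ("grm", "nrm") for n in range(1, 6)]
    return ScenarioConfig(name="fig1", kind="random", genome=_genome(scale),
                          design=_design(scale), cells=cells,
                          n_replicates=_nrep(scale), scale=scale)


def _fig2(scale: str) -> ScenarioConfig:
    cells = [Cell(label=f"rho{r:+.1f}", rho_a=r) for r in (-0.5, 0.0, 0.5)]
    return ScenarioConfig(name="fig2", kind="random", genome=_genome(scale),
                          design=_design(scale), cells=cells,
                          n_replicates=_nrep(scale), scale=scale)


def _fig3(scale: str) -> ScenarioConfig:
    cells = [Cell(label=a, allocation=a)
             for a in ("RND", "CLS", "AST", "DIS")]
    # family-allocation contrasts phenotype only the family-structured
    # generation: founders have no sire family to cluster by
    design = dataclasses.replace(_design(scale), phenotyped_generations=(1,))
    return ScenarioConfig(name="fig3", kind="random", genome=_genome(scale),
                          design=design, cells=cells,
                          n_replicates=_nrep(scale), scale=scale)


def _fig4(scale: str) -> ScenarioConfig:
    cells = [Cell(label="known", x_source="known")]
    cells += [Cell(label=f"unknown{int(e * 100)}_{a}", x_source="two_step",
                   epsilon=e, allocation=a)
              for e in (0.1, 0.2, 0.3, 0.5) for a in ("RND", "CLS", "AST")]
    design = dataclasses.replace(_design(scale), phenotyped_generations=(1,))
    return ScenarioConfig(name="fig4", kind="random", genome=_genome(scale),
                          design=design, cells=cells,
                          n_replicates=_nrep(scale), scale=scale)


def _selection_cfgs(scale: str) -> list[SelectionConfig]:
    make = SelectionConfig.desk if scale == "desk" else SelectionConfig
    cfgs = [make(alpha=a) for a in np.round(np.linspace(0, 1, 11), 2)]
    cfgs.append(make(criterion="conventional"))
    return cfgs


def _fig5(scale: str) -> ScenarioConfig:
    cfgs = _selection_cfgs(scale)
    envs = [EnvConfig(x_range=(0.0, 2.0)) for _ in cfgs]
    return ScenarioConfig(name="fig5", kind="selection", genome=_genome(scale),
                          selection=cfgs, selection_env=envs,
                          n_replicates=_nrep(scale), scale=scale)


def _fig6(scale: str) -> ScenarioConfig:
    cfgs, envs = [], []
    for rng in ((0.0, 1.0), (1.0, 2.0)):
        for c in _selection_cfgs(scale):
            cfgs.append(c)
            envs.append(EnvConfig(x_range=rng))
    return ScenarioConfig(name="fig6", kind="selection", genome=_genome(scale),
                          selection=cfgs, selection_env=envs,
                          n_replicates=_nrep(scale), scale=scale)


_PRESETS = {
    "fig1": (_fig1, "records per individual x (GBLUP, BLUP), known challenge"),
    "fig2": (_fig2, "genetic correlation sweep, GBLUP, 3 records"),
    "fig3": (_fig3, "allocation schemes RND/CLS/AST/DIS, GBLUP, 3 records"),
    "fig4": (_fig4, "unknown challenge: two-step proxy at several epsilon"),
    "fig5": (_fig5, "10-generation selection, wide challenge range [0,2]"),
    "fig6": (_fig6, "10-generation selection, narrow ranges [0,1] and [1,2]"),
}


def list_presets() -> dict[str, str]:
    """Preset catalog: name -> one-line description (desk variants implied)."""
    out = {}
    for name, (_, desc) in _PRESETS.items():
        out[name] = desc
        out[f"desk_{name}"] = f"{desc} (tenth-scale desk variant)"
    return out


def get_preset(name: str) -> ScenarioConfig:
    scale = "full"
    base = name
    if name.startswith("desk_"):
        scale, base = "desk", name[5:]
    if base not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}")
    return _PRESETS[base][0](scale)
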