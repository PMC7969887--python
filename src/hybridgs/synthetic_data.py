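"""Synthetic breeding populations with full ground truth.

The generator emulates the structure of an inbred-line hybrid-breeding
program: heterozygous outbred founders are intercrossed for a few cycles
of random mating, inbred lines are then derived by single seed descent
(SSD, one selfed offspring per generation), and F1 hybrids are produced
by crossing pairs of inbred lines.  Meiosis uses the minimal standard
model — independent assortment between chromosomes plus Poisson
crossovers within, on a uniform genetic map.

Quantitative traits get a sparse QTL architecture with additive effects
and dominance deviations; effect sizes are rescaled so the realized
variance components in the reference population hit their targets
exactly, which makes parameter-recovery tests sharp.

Default dimensions follow the emulated study geometry: 22 founders,
3 intercross cycles, 105 lines from 4 SSD generations, 275 random F1
crosses, and five traits with additive-plus-dominance heritabilities in
the 0.6-0.8 range.  The default marker count is 2,000 — enough for the
kinships and prediction models to behave like a dense panel while
keeping a full pipeline run desk-scale; the real panel size is a config
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix
from .hybrid_genotypes import CrossPlan, hybrid_id, sample_plan
from .relationship_matrices import heterozygosity_design

__all__ = [
    "TraitArchitecture",
    "SimConfig",
    "SimTruth",
    "Population",
    "simulate_founders",
    "random_intercross",
    "single_seed_descent",
    "cross_pairs",
    "assign_trait_architecture",
    "simulate_phenotypes",
    "leaf_area_index",
    "pericarp_color_index",
    "simulate_breeding_population",
]


@dataclass
class TraitArchitecture:
    """Target genetic architecture of one trait (variances on the trait
    scale; dominance deviations are degree-of-dominance x |additive|)."""

    name: str
    n_qtl: int = 100
    sigma2_A: float = 0.6
    sigma2_D: float = 0.1
    sigma2_e: float = 0.3
    dominance_degree_mean: float = 0.5
    dominance_degree_sd: float = 0.25
    env_shift_sd: float = 0.0


def _default_traits() -> list[TraitArchitecture]:
    # five traits with additive-plus-dominance heritabilities spanning the
    # 0.6-0.8 range typical of well-replicated fruit and vegetative traits
    specs = [
        ("petiole_length", 0.70, 0.03, 0.27),
        ("leaf_area", 0.73, 0.05, 0.22),
        ("brix", 0.69, 0.07, 0.24),
        ("fruit_hardness", 0.60, 0.09, 0.31),
        ("pericarp_color", 0.72, 0.06, 0.22),
    ]
    return [TraitArchitecture(n, sigma2_A=a, sigma2_D=d, sigma2_e=e)
            for n, a, d, e in specs]


@dataclass
class SimConfig:
    n_founders: int = 22
    intercross_cycles: int = 3
    intercross_size: int = 200
    selfing_generations: int = 4
    n_lines: int = 105
    n_markers: int = 2000
    n_chromosomes: int = 7
    chromosome_morgans: float = 1.0
    chromosome_bp: int = 30_000_000
    n_crosses: int = 275
    maf_low: float = 0.1
    maf_high: float = 0.9
    retained_het_fraction: float = 0.0
    traits: list[TraitArchitecture] = field(default_factory=_default_traits)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "intercross_size", "n_lines",
                     "n_markers", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for t in self.traits:
            if min(t.sigma2_A, t.sigma2_D, t.sigma2_e) < 0:
                raise ValueError("variance targets must be >= 0")


@dataclass
class Population:
    """Phased diploid genotypes: ``haplotypes[(i, m, k)]`` is allele k of
    individual i at marker m, alleles coded {0 = ref, 1 = alt}."""

    ids: list[str]
    markers: pd.DataFrame
    haplotypes: np.ndarray  # (n, m, 2) int8
    chromosome_morgans: float = 1.0

    @property
    def n(self) -> int:
        return len(self.ids)

    def chromosome_slices(self) -> list[slice]:
        chrom = self.markers["chrom"].to_numpy()
        slices = []
        start = 0
        for c in pd.unique(chrom):
            n = int((chrom == c).sum())
            slices.append(slice(start, start + n))
            start += n
        return slices

    def to_genotype_matrix(self) -> GenotypeMatrix:
        calls = self.haplotypes.sum(axis=2).astype(np.int8) - 1
        return GenotypeMatrix(list(self.ids), self.markers.copy(), calls)


@dataclass
class SimTruth:
    """Ground truth for one simulated trait."""

    name: str
    qtl_indices: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    genetic_values: pd.Series
    realized: dict[str, float]

    def genetic_values_for(self, G: GenotypeMatrix) -> pd.Series:
        """True genetic value of any genotypes over the same marker set."""
        Xq = G.calls[:, self.qtl_indices].astype(np.float64)
        Hq = heterozygosity_design(G)[:, self.qtl_indices]
        vals = Xq @ self.additive_effects + Hq @ self.dominance_effects
        return pd.Series(vals, index=G.individuals, name=self.name)


# ---------------------------------------------------------------------------
# Founders and meiosis
# ---------------------------------------------------------------------------

def _marker_frame(config: SimConfig) -> pd.DataFrame:
    per = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per[: config.n_markers % config.n_chromosomes] += 1
    rows = []
    for c, k in enumerate(per, start=1):
        pos = np.linspace(1, config.chromosome_bp, k).astype(np.int64)
        for j, p in enumerate(pos):
            rows.append((f"chr{c}_{j + 1}", f"chr{c}", int(p), "A", "T"))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None) -> Population:
    """Outbred heterozygous founders at Hardy-Weinberg proportions.

    Alt-allele frequencies are drawn uniformly on (maf_low, maf_high);
    each founder haplotype carries independent Bernoulli(p) alleles, so
    founder heterozygosity is 2p(1-p) in expectation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    markers = _marker_frame(config)
    p = rng.uniform(config.maf_low, config.maf_high, size=config.n_markers)
    haps = (rng.random((config.n_founders, config.n_markers, 2))
            < p[None, :, None]).astype(np.int8)
    ids = [f"FND{i + 1:03d}" for i in range(config.n_founders)]
    return Population(ids, markers, haps, config.chromosome_morgans)


def _gamete(hap: np.ndarray, slices: list[slice], morgans: float,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete: per chromosome, a random starting haplotype
    (independent assortment) with Poisson(morgans) crossovers at uniform
    genetic-map positions."""
    m = hap.shape[0]
    out = np.empty(m, dtype=np.int8)
    for sl in slices:
        k = sl.stop - sl.start
        cur = int(rng.integers(2))
        n_co = int(rng.poisson(morgans))
        if n_co == 0 or k == 1:
            choice = np.full(k, cur, dtype=np.int8)
        else:
            breaks = np.sort(rng.integers(1, k, size=n_co))
            choice = np.empty(k, dtype=np.int8)
            prev = 0
            for b in np.append(breaks, k):
                choice[prev:b] = cur
                cur = 1 - cur
                prev = b
        out[sl] = hap[sl, :][np.arange(k), choice]
    return out


def cross_pairs(pop: Population, pairs: list[tuple[int, int]],
                ids: list[str], rng: np.random.Generator) -> Population:
    """Offspring population from (row-index) parent pairs, one sampled
    gamete per parent."""
    slices = pop.chromosome_slices()
    m = pop.haplotypes.shape[1]
    haps = np.empty((len(pairs), m, 2), dtype=np.int8)
    for i, (p1, p2) in enumerate(pairs):
        haps[i, :, 0] = _gamete(pop.haplotypes[p1], slices,
                                pop.chromosome_morgans, rng)
        haps[i, :, 1] = _gamete(pop.haplotypes[p2], slices,
                                pop.chromosome_morgans, rng)
    return Population(list(ids), pop.markers.copy(), haps,
                      pop.chromosome_morgans)


def random_intercross(pop: Population, cycles: int, size: int | None = None,
                      rng: np.random.Generator | None = None,
                      seed: int = 0) -> Population:
    """Cycles of random mating (distinct parents, uniform pair sampling)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    if cycles == 0:
        return pop
    if pop.n < 2:
        raise ValueError("need at least 2 individuals to intercross")
    size = pop.n if size is None else size
    for cyc in range(cycles):
        pairs = []
        for _ in range(size):
            i, j = rng.choice(pop.n, size=2, replace=False)
            pairs.append((int(i), int(j)))
        ids = [f"IC{cyc + 1}_{k + 1:04d}" for k in range(size)]
        pop = cross_pairs(pop, pairs, ids, rng)
    return pop


def single_seed_descent(pop: Population, generations: int,
                        rng: np.random.Generator | None = None,
                        seed: int = 0,
                        retained_het_fraction: float = 0.0,
                        line_prefix: str = "IL") -> GenotypeMatrix:
    """Derive inbred lines by selfing, one offspring kept per generation.

    ``retained_het_fraction`` > 0 marks that fraction of loci as immune to
    fixation (a phenomenological stand-in for loci kept heterozygous by
    inbreeding depression): at immune loci a heterozygous parent always
    passes heterozygosity on, so realized homozygosity falls below the
    1 - (1/2)^t expectation.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    slices = pop.chromosome_slices()
    m = pop.haplotypes.shape[1]
    immune = np.zeros(m, dtype=bool)
    if retained_het_fraction > 0:
        k = int(round(retained_het_fraction * m))
        immune[rng.choice(m, size=k, replace=False)] = True
    haps = pop.haplotypes.copy()
    for _ in range(generations):
        new = np.empty_like(haps)
        for i in range(haps.shape[0]):
            parent = haps[i]
            new[i, :, 0] = _gamete(parent, slices, pop.chromosome_morgans, rng)
            new[i, :, 1] = _gamete(parent, slices, pop.chromosome_morgans, rng)
            if retained_het_fraction > 0:
                was_het = parent[:, 0] != parent[:, 1]
                lock = immune & was_het
                new[i, lock, 0] = 0
                new[i, lock, 1] = 1
        haps = new
    ids = [f"{line_prefix}{i + 1:03d}" for i in range(pop.n)]
    out = Population(ids, pop.markers.copy(), haps, pop.chromosome_morgans)
    return out.to_genotype_matrix()


def sample_f1_population(pop_parents: Population, plan: CrossPlan,
                         rng: np.random.Generator) -> Population:
    """True (gamete-sampled) F1 genotypes for the planned crosses."""
    row = {ind: i for i, ind in enumerate(pop_parents.ids)}
    pairs = [(row[p1], row[p2]) for p1, p2 in plan.pairs]
    ids = [hybrid_id(p1, p2) for p1, p2 in plan.pairs]
    return cross_pairs(pop_parents, pairs, ids, rng)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def assign_trait_architecture(G_all: GenotypeMatrix, arch: TraitArchitecture,
                              seed: int = 0) -> SimTruth:
    """Sample QTL and effects; rescale so realized variance components in
    ``G_all`` (the reference population) hit the targets exactly.

    True genetic value = sum_q a_q * dosage_q + d_q * het_q, matching the
    {-1,0,1} / {0,1,0} parameterization of the prediction models.
    """
    if arch.n_qtl > G_all.n_markers:
        raise ValueError("more QTL than markers")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(G_all.n_markers, size=arch.n_qtl, replace=False))
    a = rng.standard_normal(arch.n_qtl)
    degree = rng.normal(arch.dominance_degree_mean,
                        arch.dominance_degree_sd, size=arch.n_qtl)
    d = degree * np.abs(a)

    X = G_all.calls[:, qtl].astype(np.float64)
    H = heterozygosity_design(G_all)[:, qtl]
    u_A = X @ a
    if arch.sigma2_A > 0:
        v = u_A.var()
        if v <= 0:
            raise ValueError("no additive variance achievable (monomorphic QTL)")
        a = a * np.sqrt(arch.sigma2_A / v)
    else:
        a = np.zeros_like(a)
    u_D = H @ d
    if arch.sigma2_D > 0:
        v = u_D.var()
        if v <= 0:
            raise ValueError(
                "sigma2_D target > 0 but the population has no "
                "heterozygosity at the sampled QTL")
        d = d * np.sqrt(arch.sigma2_D / v)
    else:
        d = np.zeros_like(d)

    gv = X @ a + H @ d
    realized = {
        "sigma2_A": float((X @ a).var()),
        "sigma2_D": float((H @ d).var()),
        "sigma2_e": arch.sigma2_e,
    }
    return SimTruth(arch.name, qtl, a, d,
                    pd.Series(gv, index=G_all.individuals, name=arch.name),
                    realized)


def simulate_phenotypes(truth: SimTruth, sigma2_e: float, seed: int = 0,
                        mu: float = 0.0,
                        env_shift: float = 0.0) -> pd.Series:
    """Phenotype = mu + genetic value + N(0, sigma2_e) + optional
    population-wide environment shift (e.g. a year effect)."""
    rng = np.random.default_rng(seed)
    g = truth.genetic_values
    noise = rng.normal(0.0, np.sqrt(sigma2_e), size=len(g)) if sigma2_e > 0 \
        else np.zeros(len(g))
    return pd.Series(mu + g.to_numpy() + noise + env_shift,
                     index=g.index, name=truth.name)


def leaf_area_index(length_cm, width_cm):
    """Ellipse approximation of leaf area: length x width x 3.14."""
    return np.asarray(length_cm) * np.asarray(width_cm) * 3.14


def pericarp_color_index(L, a, b):
    """Colorimeter index L* x b* / a*."""
    a = np.asarray(a, dtype=float)
    if np.any(a == 0):
        raise ValueError("a* must be nonzero")
    return np.asarray(L) * np.asarray(b) / a


# ---------------------------------------------------------------------------
# End-to-end population
# ---------------------------------------------------------------------------

@dataclass
class BreedingSimulation:
    """Everything the pipeline consumes, with ground truth."""

    config: SimConfig
    inbred_pop: Population
    G_inbreds: GenotypeMatrix
    plan: CrossPlan
    G_f1: GenotypeMatrix            # true, gamete-sampled F1 genotypes
    truths: dict[str, SimTruth]
    phenotypes_inbreds: pd.DataFrame
    phenotypes_f1: pd.DataFrame


def simulate_breeding_population(config: SimConfig) -> BreedingSimulation:
    """Run the full emulated breeding scheme.

    Founders -> random intercross cycles -> sample lines -> SSD inbreeding
    -> random F1 cross plan -> true F1 genotypes -> traits with
    additive+dominance architecture anchored in the combined
    inbred + F1 reference population.
    """
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    mixed = random_intercross(founders, config.intercross_cycles,
                              size=config.intercross_size, rng=rng)
    keep = rng.choice(mixed.n, size=config.n_lines, replace=False)
    selected = Population([mixed.ids[i] for i in keep], mixed.markers.copy(),
                          mixed.haplotypes[keep], mixed.chromosome_morgans)
    # inbreed with phased output so true F1 gametes can be sampled
    slices = selected.chromosome_slices()
    haps = selected.haplotypes.copy()
    m = haps.shape[1]
    immune = np.zeros(m, dtype=bool)
    if config.retained_het_fraction > 0:
        k = int(round(config.retained_het_fraction * m))
        immune[rng.choice(m, size=k, replace=False)] = True
    for _ in range(config.selfing_generations):
        new = np.empty_like(haps)
        for i in range(haps.shape[0]):
            parent = haps[i]
            new[i, :, 0] = _gamete(parent, slices,
                                   selected.chromosome_morgans, rng)
            new[i, :, 1] = _gamete(parent, slices,
                                   selected.chromosome_morgans, rng)
            if config.retained_het_fraction > 0:
                was_het = parent[:, 0] != parent[:, 1]
                lock = immune & was_het
                new[i, lock, 0] = 0
                new[i, lock, 1] = 1
        haps = new
    ids = [f"IL{i + 1:03d}" for i in range(selected.n)]
    inbred_pop = Population(ids, selected.markers.copy(), haps,
                            selected.chromosome_morgans)
    G_inbreds = inbred_pop.to_genotype_matrix()

    plan = sample_plan(ids, config.n_crosses,
                       seed=int(rng.integers(2**31 - 1)))
    f1_pop = sample_f1_population(inbred_pop, plan, rng)
    G_f1 = f1_pop.to_genotype_matrix()

    G_all = G_inbreds.concat_individuals(G_f1)
    truths: dict[str, SimTruth] = {}
    phen_i = {}
    phen_f = {}
    for t, arch in enumerate(config.traits):
        truth = assign_trait_architecture(
            G_all, arch, seed=int(rng.integers(2**31 - 1)))
        truths[arch.name] = truth
        y = simulate_phenotypes(truth, arch.sigma2_e,
                                seed=int(rng.integers(2**31 - 1)))
        phen_i[arch.name] = y.loc[G_inbreds.individuals]
        phen_f[arch.name] = y.loc[G_f1.individuals]
    return BreedingSimulation(
        config, inbred_pop, G_inbreds, plan, G_f1, truths,
        pd.DataFrame(phen_i), pd.DataFrame(phen_f))
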