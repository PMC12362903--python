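"""Forward-in-time simulation of a selected livestock population.

The simulator emulates a classic two-phase breeding-population design:

1. A long *historic* phase of random mating with a shrinking population size
   (a bottleneck) followed by a rapid expansion.  Starting from founders whose
   alleles are drawn at frequency 0.5, genetic drift over thousands of
   generations produces linkage disequilibrium and a U-shaped allele-frequency
   spectrum, as observed in livestock genomes.
2. A *recent* phase of truncation selection: a small number of sires and a
   large number of dams are selected each generation on a pseudo estimated
   breeding value (EBV) that is correlated with the true breeding value (TBV)
   at a fixed accuracy.

The trait is fully additive: a subset of loci are quantitative trait loci
(QTL) with allelic substitution effects drawn from a heavy-tailed gamma
distribution (shape 0.42) with random sign, rescaled so that the TBV variance
in the unselected generation-0 population equals the target additive genetic
variance; heritability defaults to 0.25.

Recombination follows the Haldane (no-interference) model: crossover counts
per chromosome are Poisson with mean equal to the map length in Morgans and
breakpoints are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeMap",
    "Population",
    "TraitArchitecture",
    "PopulationSchedule",
    "SimulationConfig",
    "Dataset",
    "StudyDatasets",
    "StudyData",
    "init_founders",
    "meiosis",
    "random_mating_generation",
    "run_historic_phase",
    "assign_trait",
    "compute_tbv",
    "simulate_phenotype",
    "pseudo_ebv",
    "run_selection_phase",
    "build_datasets",
    "segregating_loci",
    "simulate_study",
]

MALE, FEMALE = 0, 1


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeMap:
    """Ordered map of loci over equally sized chromosomes.

    Parameters
    ----------
    chromosome : int array, chromosome index (0-based) per locus, non-decreasing.
    position_cM : float array, genetic position within the chromosome.
    is_qtl : bool array, True for causal loci, False for SNP markers.
    chrom_length_cM : map length shared by all chromosomes.
    n_chromosomes : number of chromosomes.
    """

    chromosome: np.ndarray
    position_cM: np.ndarray
    is_qtl: np.ndarray
    chrom_length_cM: float
    n_chromosomes: int

    def __post_init__(self):
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position_cM, dtype=np.float64)
        isq = np.asarray(self.is_qtl, dtype=bool)
        if not (len(chrom) == len(pos) == len(isq)):
            raise ValueError("chromosome, position_cM and is_qtl must be equal length")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("loci must be grouped by chromosome in increasing order")
        if chrom.size and (chrom.min() < 0 or chrom.max() >= self.n_chromosomes):
            raise ValueError("chromosome index out of range")
        if np.any(pos < 0) or np.any(pos > self.chrom_length_cM):
            raise ValueError("position outside [0, chrom_length_cM]")
        for c in range(self.n_chromosomes):
            pc = pos[chrom == c]
            if np.any(np.diff(pc) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cM", pos)
        object.__setattr__(self, "is_qtl", isq)
        # chromosome block boundaries and a global coordinate used for
        # mapping crossover breakpoints to locus intervals
        starts = np.searchsorted(chrom, np.arange(self.n_chromosomes + 1))
        object.__setattr__(self, "_chrom_start", starts)
        object.__setattr__(self, "_global_pos", chrom * self.chrom_length_cM + pos)

    @property
    def n_loci(self) -> int:
        return len(self.position_cM)

    @property
    def qtl_loci(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def snp_loci(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def locus_class(self) -> np.ndarray:
        return np.where(self.is_qtl, "QTL", "SNP")

    @property
    def locus_ids(self) -> np.ndarray:
        """Human-readable ids, e.g. ``c03_p012.345_QTL``."""
        return np.array(
            [
                f"c{c + 1:02d}_p{p:07.3f}_{'QTL' if q else 'SNP'}"
                for c, p, q in zip(self.chromosome, self.position_cM, self.is_qtl)
            ]
        )

    @classmethod
    def random(
        cls,
        n_chromosomes: int = 29,
        chrom_length_cM: float = 100.0,
        n_qtl_per_chromosome: int = 350,
        n_snp_per_chromosome: int = 2000,
        seed=None,
    ) -> "GenomeMap":
        """Place QTL and SNPs at uniform-random positions on each chromosome."""
        rng = _rng(seed)
        n_per = n_qtl_per_chromosome + n_snp_per_chromosome
        chrom, pos, isq = [], [], []
        for c in range(n_chromosomes):
            while True:
                p = np.sort(rng.uniform(0.0, chrom_length_cM, n_per))
                if np.all(np.diff(p) > 0):
                    break
            q = np.zeros(n_per, dtype=bool)
            q[rng.choice(n_per, n_qtl_per_chromosome, replace=False)] = True
            chrom.append(np.full(n_per, c))
            pos.append(p)
            isq.append(q)
        return cls(
            np.concatenate(chrom),
            np.concatenate(pos),
            np.concatenate(isq),
            chrom_length_cM,
            n_chromosomes,
        )


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """A cohort of diploid individuals with pedigree links and trait values.

    ``haplotypes`` has shape (n, 2, n_loci) with 0/1 alleles; it may be None
    for cohorts whose genotypes were dropped to save memory (trait summaries
    are kept).  Sex is coded 0 = male, 1 = female.
    """

    haplotypes: np.ndarray | None
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    tbv: np.ndarray | None = None
    phenotype: np.ndarray | None = None
    ebv: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Additive allele counts (0/1/2), optionally for a subset of loci."""
        if self.haplotypes is None:
            raise ValueError("haplotypes were dropped for this cohort")
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.uint8)

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        return self.dosages(loci).mean(axis=0) / 2.0

    def subset(self, idx: np.ndarray) -> "Population":
        take = lambda a: None if a is None else a[idx]
        return Population(
            take(self.haplotypes), self.ids[idx], self.sire[idx], self.dam[idx],
            self.sex[idx], self.generation[idx], take(self.tbv),
            take(self.phenotype), take(self.ebv),
        )

    def drop_haplotypes(self) -> "Population":
        return replace(self, haplotypes=None)


def _equal_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sex = np.full(n, FEMALE, dtype=np.int8)
    sex[: n // 2] = MALE
    return rng.permutation(sex)


def init_founders(n: int, genome: GenomeMap, seed=None) -> Population:
    """Founder cohort with independent Bernoulli(0.5) alleles and equal sexes."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n % 2:
        raise ValueError("founder count must be even for an equal sex ratio")
    rng = _rng(seed)
    haps = rng.integers(0, 2, size=(n, 2, genome.n_loci), dtype=np.uint8)
    sex = np.full(n, FEMALE, dtype=np.int8)
    sex[: n // 2] = MALE
    return Population(
        haplotypes=haps,
        ids=np.arange(n, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
        sex=sex,
        generation=np.zeros(n, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _gametes(parent_haps: np.ndarray, genome: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of ``parent_haps`` (shape (k, 2, L) -> (k, L)).

    Crossover counts per chromosome are Poisson(length in Morgans) with
    uniform breakpoints and no interference; each chromosome starts on a
    fair-coin parental haplotype.  Vectorised over gametes by accumulating
    crossover parity along each chromosome.
    """
    k, _, L = parent_haps.shape
    nc = genome.n_chromosomes
    len_M = genome.chrom_length_cM / 100.0
    counts = rng.poisson(len_M, size=(k, nc))
    total = int(counts.sum())
    flips = np.zeros((k, L), dtype=np.uint8)
    if total:
        g_idx = np.repeat(np.arange(k), counts.sum(axis=1))
        c_idx = np.repeat(np.tile(np.arange(nc), k), counts.ravel())
        x = rng.uniform(0.0, genome.chrom_length_cM, size=total)
        gx = c_idx * genome.chrom_length_cM + x
        loc = np.searchsorted(genome._global_pos, gx, side="left")
        # a crossover beyond the last locus of its chromosome has no effect
        ok = loc < L
        ok &= genome.chromosome[np.minimum(loc, L - 1)] == c_idx
        np.add.at(flips, (g_idx[ok], loc[ok]), 1)
    starts = rng.integers(0, 2, size=(k, nc), dtype=np.uint8)
    origin = np.empty((k, L), dtype=np.uint8)
    for c in range(nc):
        s = slice(genome._chrom_start[c], genome._chrom_start[c + 1])
        block = np.cumsum(flips[:, s], axis=1, dtype=np.uint8)  # parity survives wrap
        origin[:, s] = (starts[:, c : c + 1] + block) & 1
    rows = np.arange(k)[:, None]
    return parent_haps[rows, origin.astype(np.intp), np.arange(L)[None, :]]


def meiosis(parent_haplotypes: np.ndarray, genome: GenomeMap, seed=None) -> np.ndarray:
    """Single gamete from one parent's (2, n_loci) haplotype pair."""
    h = np.asarray(parent_haplotypes, dtype=np.uint8)
    if h.shape != (2, genome.n_loci):
        raise ValueError("parent haplotypes must have shape (2, n_loci)")
    return _gametes(h[None], genome, _rng(seed))[0]


def random_mating_generation(
    pop: Population,
    n_offspring: int,
    genome: GenomeMap,
    rng: np.random.Generator,
    generation: int,
    id_start: int,
) -> Population:
    """One discrete generation of random mating (used in the historic phase)."""
    males, females = pop.males, pop.females
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both sexes required for mating")
    sires = rng.choice(males, size=n_offspring, replace=True)
    dams = rng.choice(females, size=n_offspring, replace=True)
    pat = _gametes(pop.haplotypes[sires], genome, rng)
    mat = _gametes(pop.haplotypes[dams], genome, rng)
    return Population(
        haplotypes=np.stack([pat, mat], axis=1),
        ids=id_start + np.arange(n_offspring, dtype=np.int64),
        sire=pop.ids[sires],
        dam=pop.ids[dams],
        sex=_equal_sexes(n_offspring, rng),
        generation=np.full(n_offspring, generation, dtype=np.int64),
    )


def mutate(
    pop: Population,
    genome: GenomeMap,
    rng: np.random.Generator,
    snp_rate: float = 0.0,
    qtl_rate: float = 0.0,
) -> None:
    """Recurrent allele-flip mutation, in place, at per-allele rates per class.

    Marker panels are ascertained for polymorphism; recurrent mutation at SNP
    loci during the historic phase keeps the marker spectrum U-shaped and
    mostly segregating, while QTL (no mutation by default) drift and fix.
    Simultaneous double hits at one slot are ignored (negligible at the rates
    used).
    """
    for loci, rate in ((genome.snp_loci, snp_rate), (genome.qtl_loci, qtl_rate)):
        if rate <= 0 or len(loci) == 0:
            continue
        slots = pop.n * 2 * len(loci)
        k = rng.binomial(slots, rate)
        if k == 0:
            continue
        rows = rng.integers(0, pop.n, size=k)
        which = rng.integers(0, 2, size=k)
        cols = loci[rng.integers(0, len(loci), size=k)]
        pop.haplotypes[rows, which, cols] ^= 1


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSchedule:
    """Population sizes and selection design.

    ``historic_anchors`` are (generation, size) knots; sizes between knots are
    linearly interpolated (and rounded to even counts so the sex ratio stays
    exact).  The recent phase runs ``n_generations`` generations in which each
    of ``n_dams`` dams produces exactly one offspring from a randomly assigned
    sire among ``n_sires``; all sires and half of the dams are replaced each
    generation, selected on pseudo-EBVs of accuracy ``ebv_accuracy``.
    """

    historic_anchors: tuple = ((1, 2800), (2250, 2000), (2500, 200), (2505, 10000))
    n_generations: int = 20
    n_sires: int = 20
    n_dams: int = 5000
    ebv_accuracy: float = 0.8

    def historic_sizes(self) -> np.ndarray:
        gens = np.array([g for g, _ in self.historic_anchors], dtype=float)
        sizes = np.array([s for _, s in self.historic_anchors], dtype=float)
        if np.any(np.diff(gens) <= 0):
            raise ValueError("anchor generations must be strictly increasing")
        grid = np.arange(gens[0], gens[-1] + 1)
        out = np.interp(grid, gens, sizes)
        out = np.rint(out).astype(np.int64)
        out += out % 2  # even sizes keep the sex ratio exact
        return out

    @classmethod
    def full(cls) -> "PopulationSchedule":
        return cls()

    @classmethod
    def mini(cls) -> "PopulationSchedule":
        return cls(
            historic_anchors=((1, 280), (250, 200), (280, 50), (300, 1000)),
            n_generations=20,
            n_sires=10,
            n_dams=500,
            ebv_accuracy=0.8,
        )


def run_historic_phase(
    schedule: PopulationSchedule,
    genome: GenomeMap,
    seed=None,
    snp_mutation_rate: float = 0.0,
    qtl_mutation_rate: float = 0.0,
) -> Population:
    """Random-mating historic phase; returns the final cohort as generation 0."""
    rng = _rng(seed)
    sizes = schedule.historic_sizes()
    pop = init_founders(int(sizes[0]), genome, rng)
    next_id = pop.n
    for t in range(1, len(sizes)):
        pop = random_mating_generation(pop, int(sizes[t]), genome, rng, t, next_id)
        mutate(pop, genome, rng, snp_mutation_rate, qtl_mutation_rate)
        next_id += pop.n
    pop.generation = np.zeros(pop.n, dtype=np.int64)
    return pop


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL positions and effects plus trait variance components.

    ``effects`` are allelic substitution effects aligned to ``qtl_loci``
    (indices into the genome map); heritability is defined on the unselected
    generation-0 population.
    """

    qtl_loci: np.ndarray
    effects: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float

    def __post_init__(self):
        expect = self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)
        if abs(expect - self.h2) > 1e-8:
            raise ValueError("h2 inconsistent with sigma_g2 / (sigma_g2 + sigma_e2)")


def assign_trait(
    pop: Population,
    genome: GenomeMap,
    gamma_shape: float = 0.42,
    h2: float = 0.25,
    sigma_g2: float = 1.0,
    seed=None,
) -> TraitArchitecture:
    """Sample signed gamma QTL effects, scaled so Var(TBV) in ``pop`` = sigma_g2."""
    rng = _rng(seed)
    qtl = genome.qtl_loci
    eff = rng.gamma(gamma_shape, 1.0, size=len(qtl))
    eff *= rng.choice([-1.0, 1.0], size=len(qtl))
    g = pop.dosages(qtl).astype(np.float64) @ eff
    v = g.var()
    if v <= 0:
        raise ValueError("no segregating QTL: TBV variance is zero")
    eff *= np.sqrt(sigma_g2 / v)
    sigma_e2 = sigma_g2 * (1.0 - h2) / h2
    return TraitArchitecture(qtl.copy(), eff, float(sigma_g2), float(sigma_e2), float(h2))


def compute_tbv(dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """TBV = sum over QTL of dosage times allelic effect.

    ``dosages`` may be the full animals x loci matrix (QTL columns are taken
    from ``arch.qtl_loci``) or already restricted to the QTL columns in
    architecture order.
    """
    X = np.asarray(dosages)
    nq = len(arch.qtl_loci)
    if X.shape[1] == nq:
        Xq = X
    elif X.shape[1] > int(arch.qtl_loci.max()):
        Xq = X[:, arch.qtl_loci]
    else:
        raise ValueError("genotype matrix does not cover all QTL columns")
    return Xq.astype(np.float64) @ arch.effects


def simulate_phenotype(tbv: np.ndarray, sigma_e2: float, seed=None) -> np.ndarray:
    if sigma_e2 < 0:
        raise ValueError("sigma_e2 must be non-negative")
    rng = _rng(seed)
    return tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=len(tbv))


def pseudo_ebv(tbv: np.ndarray, accuracy: float = 0.8, seed=None) -> np.ndarray:
    """Selection index correlated with TBV at the given accuracy.

    ebv = mean + r (tbv - mean) + sqrt(1 - r^2) sd eps, so the within-cohort
    correlation with TBV equals r.  Stands in for a pedigree BLUP whose
    accuracy is specified rather than modelled.  The index is kept on the
    trait scale (cohort mean added back) so EBVs remain comparable across
    cohorts: a mixed-age dam herd must rank old elite dams against younger
    candidates that carry the genetic trend, exactly as trait-scale EBVs do.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    rng = _rng(seed)
    m, sd = tbv.mean(), tbv.std()
    noise = np.sqrt(1.0 - accuracy**2) * sd * rng.standard_normal(len(tbv))
    return m + accuracy * (tbv - m) + noise


# ---------------------------------------------------------------------------
# selection phase
# ---------------------------------------------------------------------------


def _top(pop: Population, idx: np.ndarray, k: int, what: str) -> Population:
    if len(idx) < k:
        raise ValueError(f"not enough {what}: need {k}, have {len(idx)}")
    order = idx[np.argsort(pop.ebv[idx])[::-1][:k]]
    return pop.subset(order)


def run_selection_phase(
    pop0: Population,
    arch: TraitArchitecture,
    genome: GenomeMap,
    schedule: PopulationSchedule,
    seed=None,
    keep_haplotypes: Iterable[int] | None = None,
) -> dict[int, Population]:
    """Truncation selection for ``schedule.n_generations`` generations.

    Each generation, every dam produces one offspring with a random sire; the
    top ``n_sires`` male offspring replace all sires, and the dam herd keeps
    its best half plus the best female offspring.  If ``keep_haplotypes`` is
    given, haplotypes of cohorts outside that set are dropped (trait values
    are always kept).
    """
    rng = _rng(seed)
    if pop0.ebv is None:
        raise ValueError("generation-0 population must carry pseudo-EBVs")
    keep = None if keep_haplotypes is None else set(keep_haplotypes)
    sires = _top(pop0, pop0.males, schedule.n_sires, "male candidates")
    dams = _top(pop0, pop0.females, schedule.n_dams, "female candidates")
    next_id = int(pop0.ids.max()) + 1
    pops: dict[int, Population] = {}
    for g in range(1, schedule.n_generations + 1):
        n_off = schedule.n_dams  # litter size 1
        sire_of = rng.integers(0, schedule.n_sires, size=n_off)
        pat = _gametes(sires.haplotypes[sire_of], genome, rng)
        mat = _gametes(dams.haplotypes, genome, rng)
        off = Population(
            haplotypes=np.stack([pat, mat], axis=1),
            ids=next_id + np.arange(n_off, dtype=np.int64),
            sire=sires.ids[sire_of],
            dam=dams.ids.copy(),
            sex=_equal_sexes(n_off, rng),
            generation=np.full(n_off, g, dtype=np.int64),
        )
        next_id += n_off
        off.tbv = compute_tbv(off.dosages(arch.qtl_loci), arch)
        off.phenotype = simulate_phenotype(off.tbv, arch.sigma_e2, rng)
        off.ebv = pseudo_ebv(off.tbv, schedule.ebv_accuracy, rng)
        # replacement: all sires, best half of dams + best female offspring
        sires = _top(off, off.males, schedule.n_sires, "male offspring")
        n_keep = schedule.n_dams // 2
        kept = _top(dams, np.arange(dams.n), n_keep, "retained dams")
        new = _top(off, off.females, schedule.n_dams - n_keep, "female offspring")
        cat = lambda a, b: None if a is None or b is None else np.concatenate([a, b])
        dams = Population(
            haplotypes=np.concatenate([kept.haplotypes, new.haplotypes]),
            ids=np.concatenate([kept.ids, new.ids]),
            sire=np.concatenate([kept.sire, new.sire]),
            dam=np.concatenate([kept.dam, new.dam]),
            sex=np.concatenate([kept.sex, new.sex]),
            generation=np.concatenate([kept.generation, new.generation]),
            tbv=np.concatenate([kept.tbv, new.tbv]),
            phenotype=cat(kept.phenotype, new.phenotype),
            ebv=np.concatenate([kept.ebv, new.ebv]),
        )
        pops[g] = off if keep is None or g in keep else off.drop_haplotypes()
    return pops


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Genotypes plus trait columns for one analysis role."""

    ids: np.ndarray
    X: np.ndarray  # animals x all loci dosages, uint8
    tbv: np.ndarray
    generation: np.ndarray
    y: np.ndarray | None = None  # phenotypes (training only)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class StudyDatasets:
    train: Dataset
    tests: dict[int, Dataset]


def _sample(pop: Population, k: int, rng, with_y: bool) -> Dataset:
    if pop.n < k:
        raise ValueError(f"generation has {pop.n} animals, cannot sample {k}")
    idx = np.sort(rng.choice(pop.n, size=k, replace=False))
    sub = pop.subset(idx)
    y = sub.phenotype if with_y else None
    if with_y and y is None:
        raise ValueError("training animals must carry phenotypes")
    return Dataset(sub.ids, sub.dosages(), sub.tbv, sub.generation, y)


def build_datasets(
    pops: Mapping[int, Population],
    train_generations: Sequence[int] = (11, 12, 13, 14, 15),
    n_train_per_generation: int = 2500,
    test_generations: Sequence[int] = (16, 17, 18, 19, 20),
    n_test_per_generation: int = 500,
    seed=None,
) -> StudyDatasets:
    """Random training/test samples; training ids and test ids are disjoint."""
    rng = _rng(seed)
    parts = [_sample(pops[g], n_train_per_generation, rng, with_y=True) for g in train_generations]
    train = Dataset(
        np.concatenate([p.ids for p in parts]),
        np.concatenate([p.X for p in parts]),
        np.concatenate([p.tbv for p in parts]),
        np.concatenate([p.generation for p in parts]),
        np.concatenate([p.y for p in parts]),
    )
    tests = {g: _sample(pops[g], n_test_per_generation, rng, with_y=False) for g in test_generations}
    return StudyDatasets(train, tests)


def segregating_loci(
    pop: Population, genome: GenomeMap | None = None, locus_class: str | None = None
) -> np.ndarray:
    """Loci with allele frequency strictly between 0 and 1 in ``pop``."""
    p = pop.allele_frequencies()
    mask = (p > 0.0) & (p < 1.0)
    if locus_class is not None:
        if genome is None:
            raise ValueError("genome required to filter by locus class")
        if locus_class == "QTL":
            mask &= genome.is_qtl
        elif locus_class == "SNP":
            mask &= ~genome.is_qtl
        else:
            raise ValueError("locus_class must be 'SNP' or 'QTL'")
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# end-to-end study simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulated study replicate."""

    n_chromosomes: int = 29
    chrom_length_cM: float = 100.0
    n_qtl_per_chromosome: int = 350
    n_snp_per_chromosome: int = 2000
    schedule: PopulationSchedule = field(default_factory=PopulationSchedule.full)
    gamma_shape: float = 0.42
    h2: float = 0.25
    sigma_g2: float = 1.0
    snp_mutation_rate: float = 2.5e-5  # historic phase, per allele per generation
    qtl_mutation_rate: float = 0.0
    train_generations: tuple = (11, 12, 13, 14, 15)
    n_train_per_generation: int = 2500
    test_generations: tuple = (16, 17, 18, 19, 20)
    n_test_per_generation: int = 500

    @classmethod
    def full_scale(cls) -> "SimulationConfig":
        return cls()

    @classmethod
    def mini_ci(cls) -> "SimulationConfig":
        """Scaled-down profile: same design, ~25x fewer animals and loci."""
        return cls(
            n_chromosomes=5,
            n_qtl_per_chromosome=70,
            n_snp_per_chromosome=400,
            schedule=PopulationSchedule.mini(),
            snp_mutation_rate=2.5e-4,  # keeps 4Nu comparable at the smaller N
            n_train_per_generation=120,
            n_test_per_generation=100,
        )


@dataclass
class StudyData:
    """One simulated replicate: genome, trait truth, and analysis datasets."""

    genome: GenomeMap
    arch: TraitArchitecture
    p0: np.ndarray  # generation-0 allele frequencies, all loci
    seg_snp: np.ndarray  # segregating SNP locus indices (generation 0)
    seg_qtl: np.ndarray  # segregating QTL locus indices (generation 0)
    datasets: StudyDatasets
    tbv_by_generation: dict[int, float]  # mean TBV per recent generation


def simulate_study(cfg: SimulationConfig, seed=None) -> StudyData:
    """Run the full two-phase simulation and assemble training/test datasets."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_map, s_hist, s_trait, s_gen0, s_sel, s_ds = [np.random.default_rng(c) for c in ss.spawn(6)]
    genome = GenomeMap.random(
        cfg.n_chromosomes, cfg.chrom_length_cM,
        cfg.n_qtl_per_chromosome, cfg.n_snp_per_chromosome, seed=s_map,
    )
    pop0 = run_historic_phase(
        cfg.schedule, genome, s_hist,
        snp_mutation_rate=cfg.snp_mutation_rate,
        qtl_mutation_rate=cfg.qtl_mutation_rate,
    )
    arch = assign_trait(pop0, genome, cfg.gamma_shape, cfg.h2, cfg.sigma_g2, s_trait)
    pop0.tbv = compute_tbv(pop0.dosages(arch.qtl_loci), arch)
    pop0.phenotype = simulate_phenotype(pop0.tbv, arch.sigma_e2, s_gen0)
    pop0.ebv = pseudo_ebv(pop0.tbv, cfg.schedule.ebv_accuracy, s_gen0)
    p0 = pop0.allele_frequencies()
    seg_snp = segregating_loci(pop0, genome, "SNP")
    seg_qtl = segregating_loci(pop0, genome, "QTL")
    keep = set(cfg.train_generations) | set(cfg.test_generations)
    pops = run_selection_phase(pop0, arch, genome, cfg.schedule, s_sel, keep_haplotypes=keep)
    datasets = build_datasets(
        pops, cfg.train_generations, cfg.n_train_per_generation,
        cfg.test_generations, cfg.n_test_per_generation, s_ds,
    )
    tbv_means = {0: float(pop0.tbv.mean())}
    tbv_means.update({g: float(p.tbv.mean()) for g, p in pops.items()})
    return StudyData(genome, arch, p0, seg_snp, seg_qtl, datasets, tbv_means)
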